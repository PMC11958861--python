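"""Patch-based L2 training of the encoder-decoder.

Training follows the published schedule: random 3D patches cropped jointly
from the paired T1/DVR volumes, Adam with an initial learning rate of 0.001
decayed by 0.99 every 100 steps (staircase), a fixed number of steps per
epoch, and the mean-squared-error loss.  Because the network uses valid
padding, the target patch is center-cropped to the network's output shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, EncoderDecoder3D, NetworkConfig, build_network, output_shape


@dataclass
class TrainingConfig:
    """Optimization hyperparameters (defaults follow the published schedule)."""

    patch_size: int = 64
    batch_size: int = 4
    steps_per_epoch: int = 100
    epochs: int = 150
    lr0: float = 1e-3
    lr_decay: float = 0.99
    lr_decay_every: int = 100
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    #: optional minimum fraction of nonzero (brain) voxels per sampled patch
    min_brain_fraction: float = 0.0
    #: restrict the L2 loss to nonzero-target (brain) voxels
    masked_loss: bool = False
    #: average the weights of the final K epochs (0 = use final weights);
    #: a tail average damps the end-of-training wander of the prediction
    #: amplitude without using validation data for selection
    tail_average_epochs: int = 0
    #: fixed validation patches drawn once at the start of training
    n_val_patches: int = 16

    def __post_init__(self):
        for name in ("patch_size", "batch_size", "steps_per_epoch", "epochs", "lr_decay_every"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.lr_decay <= 1.0:
            raise ValueError("lr_decay must be in (0, 1]")
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")


@dataclass
class LossCurve:
    """Per-epoch mean training and validation loss, plus sampler bookkeeping."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    patches_per_epoch: list[int] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"epoch": np.arange(1, len(self.train_loss) + 1),
             "train_loss": self.train_loss, "val_loss": self.val_loss}
        )


def lr_at(step: int, cfg: TrainingConfig) -> float:
    """Staircase learning rate: lr0 * decay^floor(step / decay_every)."""
    if step < 0:
        raise ValueError(f"step must be >= 0, got {step}")
    return cfg.lr0 * cfg.lr_decay ** (step // cfg.lr_decay_every)


def l2_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean of squared voxel differences."""
    pred, target = np.asarray(pred), np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    return float(np.mean((pred.astype(np.float64) - target.astype(np.float64)) ** 2))


def sample_corner(volume_shape, size: int, rng: np.random.Generator) -> tuple[int, int, int]:
    """Uniform draw over all corners where a size^3 patch fits."""
    if any(n < size for n in volume_shape):
        raise ValueError(f"volume {volume_shape} smaller than patch size {size}")
    return tuple(int(rng.integers(0, n - size + 1)) for n in volume_shape)


def center_crop(a: np.ndarray, out_shape) -> np.ndarray:
    """Crop the centered ``out_shape`` block (valid-padding target crop)."""
    slices = []
    for n, o in zip(a.shape, out_shape):
        lo = (n - o) // 2
        slices.append(slice(lo, lo + o))
    return a[tuple(slices)]


def sample_patch(pair, size: int, rng: np.random.Generator,
                 target_shape=None, min_brain_fraction: float = 0.0,
                 max_tries: int = 50):
    """Crop the same random window from both volumes of a pair.

    Returns ``(input_patch, target_patch)``; the target is center-cropped to
    ``target_shape`` (the network's valid-padding output) when given.  With
    ``min_brain_fraction`` > 0, windows whose input patch has a smaller
    fraction of nonzero voxels are redrawn (bounded by ``max_tries``).
    """
    t1, dvr = pair
    t1 = t1.values if hasattr(t1, "values") else np.asarray(t1)
    dvr = dvr.values if hasattr(dvr, "values") else np.asarray(dvr)
    if t1.shape != dvr.shape:
        raise ValueError("paired volumes must share a shape")
    for _ in range(max(1, max_tries)):
        corner = sample_corner(t1.shape, size, rng)
        sl = tuple(slice(c, c + size) for c in corner)
        xp = t1[sl]
        if min_brain_fraction <= 0 or (xp != 0).mean() >= min_brain_fraction:
            break
    yp = dvr[sl]
    if target_shape is not None:
        yp = center_crop(yp, target_shape)
    return xp, yp


def train(cohort, val, net_cfg: NetworkConfig, cfg: TrainingConfig,
          ) -> tuple[EncoderDecoder3D, LossCurve]:
    """Optimize the network on paired (T1, DVR) volumes.

    ``cohort`` and ``val`` are sequences of (t1, dvr) array pairs on the same
    grid (already masked and intensity-normalized).  Each step draws its
    batch's source participants uniformly with replacement and one random
    patch from each; epochs therefore consume batch_size * steps_per_epoch
    patches.  Validation loss is the mean L2 over a fixed set of patches
    drawn once before training.  Fully reproducible from the seeds.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("training cohort is empty")
    psize = cfg.patch_size
    out_sp, _ = output_shape(net_cfg, (psize, psize, psize))

    net_cfg.init_seed = cfg.seed
    model = build_network(net_cfg)
    opt = Adam(model.parameters(), beta1=cfg.beta1, beta2=cfg.beta2)
    rng = np.random.default_rng([cfg.seed % 2**31, 1])

    val_patches = []
    if val:
        vrng = np.random.default_rng([cfg.seed % 2**31, 2])
        for i in range(cfg.n_val_patches):
            pair = val[int(vrng.integers(0, len(val)))]
            val_patches.append(sample_patch(pair, psize, vrng, out_sp,
                                            cfg.min_brain_fraction))

    curve = LossCurve()
    tail_states: list[dict] = []
    step_idx = 0
    for _ in range(cfg.epochs):
        epoch_losses = []
        n_patches = 0
        for _ in range(cfg.steps_per_epoch):
            xs, ys = [], []
            for _ in range(cfg.batch_size):
                pair = cohort[int(rng.integers(0, len(cohort)))]
                xp, yp = sample_patch(pair, psize, rng, out_sp, cfg.min_brain_fraction)
                xs.append(xp)
                ys.append(yp)
                n_patches += 1
            xb = np.stack(xs)[:, None].astype(np.float32)
            yb = np.stack(ys)[:, None].astype(np.float32)
            pred = model.forward(xb, train=True)
            resid = pred - yb
            if cfg.masked_loss:
                w = (yb != 0).astype(np.float32)
                denom = max(float(w.sum()), 1.0)
                loss = float((resid.astype(np.float64) ** 2 * w).sum() / denom)
                grad = (2.0 / denom) * resid * w
            else:
                loss = float(np.mean(resid.astype(np.float64) ** 2))
                grad = (2.0 / resid.size) * resid
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at step {step_idx}; "
                    "reduce the learning rate or check input scaling"
                )
            model.backward(grad)
            grads = [g for _, g in model.params_grads()]
            opt.step(grads, lr_at(step_idx, cfg))
            epoch_losses.append(loss)
            step_idx += 1
        curve.train_loss.append(float(np.mean(epoch_losses)))
        if cfg.tail_average_epochs > 0:
            tail_states.append(model.state_dict())
            if len(tail_states) > cfg.tail_average_epochs:
                tail_states.pop(0)
        if val_patches:
            vloss = np.mean([
                l2_loss(model.forward(xp[None, None].astype(np.float32))[0, 0], yp)
                for xp, yp in val_patches
            ])
        else:
            vloss = np.nan
        curve.val_loss.append(float(vloss))
        curve.patches_per_epoch.append(n_patches)
    if cfg.tail_average_epochs > 0 and tail_states:
        mean_state = {k: np.mean([st[k] for st in tail_states], axis=0)
                      for k in tail_states[0]}
        model.load_state_dict(mean_state)
    return model, curve
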