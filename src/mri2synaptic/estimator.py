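"""Scikit-learn style estimator facade over the translation pipeline.

:class:`SynapticPETTranslator` wraps network construction, patch-based
training and tiled whole-volume inference behind the familiar
``fit(X, y)`` / ``predict(X)`` surface, so the model composes with sklearn
utilities (``clone``, ``get_params``/``set_params``, pipelines over
object-dtype containers).  ``X`` and ``y`` are sequences of 3D arrays: the
masked, intensity-normalized T1 volumes and their DVR targets.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .inference import plan_tiles, predict_volume
from .nn import NetworkConfig
from .training import LossCurve, TrainingConfig, train


def _as_volume_list(X) -> list[np.ndarray]:
    vols = [np.asarray(v.values if hasattr(v, "values") else v, dtype=np.float32) for v in X]
    if not vols:
        raise ValueError("expected at least one volume")
    for v in vols:
        if v.ndim != 3:
            raise ValueError(f"each sample must be a 3D volume, got ndim={v.ndim}")
    return vols


class SynapticPETTranslator(BaseEstimator):
    """3D encoder-decoder regressor from structural MRI to synaptic-density DVR.

    Parameters mirror the architecture and optimization hyperparameters; the
    published configuration is the default (encoder ladder 32/64/128/256,
    3x3x3 kernels, valid padding, 64^3 patches, batch 4, 150 x 100 steps,
    Adam at 1e-3 with 0.99 staircase decay every 100 steps).

    Attributes set by :meth:`fit` carry a trailing underscore:
    ``model_`` (the trained network), ``loss_curve_``, ``net_cfg_``,
    ``n_parameters_``.
    """

    def __init__(self, encoder_filters=(32, 64, 128, 256), kernel=3,
                 downsample_stride=2, final_relu=True, patch_size=64,
                 batch_size=4, steps_per_epoch=100, epochs=150, lr0=1e-3,
                 lr_decay=0.99, lr_decay_every=100, beta1=0.9, beta2=0.999,
                 min_brain_fraction=0.0, n_val_patches=16,
                 tile_input_shape=None, seed=0):
        self.encoder_filters = encoder_filters
        self.kernel = kernel
        self.downsample_stride = downsample_stride
        self.final_relu = final_relu
        self.patch_size = patch_size
        self.batch_size = batch_size
        self.steps_per_epoch = steps_per_epoch
        self.epochs = epochs
        self.lr0 = lr0
        self.lr_decay = lr_decay
        self.lr_decay_every = lr_decay_every
        self.beta1 = beta1
        self.beta2 = beta2
        self.min_brain_fraction = min_brain_fraction
        self.n_val_patches = n_val_patches
        self.tile_input_shape = tile_input_shape
        self.seed = seed

    def _configs(self) -> tuple[NetworkConfig, TrainingConfig]:
        enc = tuple(int(f) for f in self.encoder_filters)
        net_cfg = NetworkConfig(
            encoder_filters=enc, decoder_filters=tuple(reversed(enc)),
            kernel=self.kernel, downsample_stride=self.downsample_stride,
            final_relu=self.final_relu, init_seed=self.seed,
        )
        train_cfg = TrainingConfig(
            patch_size=self.patch_size, batch_size=self.batch_size,
            steps_per_epoch=self.steps_per_epoch, epochs=self.epochs,
            lr0=self.lr0, lr_decay=self.lr_decay, lr_decay_every=self.lr_decay_every,
            seed=self.seed, beta1=self.beta1, beta2=self.beta2,
            min_brain_fraction=self.min_brain_fraction,
            n_val_patches=self.n_val_patches,
        )
        return net_cfg, train_cfg

    def fit(self, X, y, X_val=None, y_val=None):
        """Train on paired (T1, DVR) volume lists."""
        xs, ys = _as_volume_list(X), _as_volume_list(y)
        if len(xs) != len(ys):
            raise ValueError(f"X and y lengths differ: {len(xs)} vs {len(ys)}")
        net_cfg, train_cfg = self._configs()
        val_pairs = []
        if X_val is not None and y_val is not None:
            val_pairs = list(zip(_as_volume_list(X_val), _as_volume_list(y_val)))
        model, curve = train(list(zip(xs, ys)), val_pairs, net_cfg, train_cfg)
        self.net_cfg_ = net_cfg
        self.model_ = model
        self.loss_curve_: LossCurve = curve
        self.n_parameters_ = model.n_parameters
        return self

    def predict(self, X) -> list[np.ndarray]:
        """Tiled whole-volume prediction for each input volume."""
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit first")
        out = []
        for v in _as_volume_list(X):
            # default: tile with windows the size of the training patches, so
            # inference sees the same input statistics as optimization did
            tin = self.tile_input_shape or (self.patch_size,) * 3
            plan = plan_tiles(v.shape, tin, self.net_cfg_, output_crop=None)
            out.append(predict_volume(self.model_, v, plan).values)
        return out

    def score(self, X, y) -> float:
        """Negative mean L2 across volumes (higher is better), computed on
        the valid-region crop implied by whole-volume tiling."""
        preds = self.predict(X)
        ys = _as_volume_list(y)
        return -float(np.mean([np.mean((p - t) ** 2) for p, t in zip(preds, ys)]))
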