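"""Symmetric 3D convolutional encoder-decoder for MRI-to-DVR translation.

The encoder is a ladder of strided valid convolutions that double the channel
count while downsampling; the decoder mirrors it with strided transposed
convolutions, and a final stride-1 single-channel convolution produces the
predicted DVR patch.  There are no skip connections and no pooling layers.
Because every layer uses valid padding, the spatial output is smaller than
the input; :func:`output_shape` gives the exact per-layer arithmetic and
callers center-crop training targets (or tile whole volumes) accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import Conv3D, ConvTranspose3D, conv_out_len, conv_transpose_out_len


class InadmissibleShapeError(ValueError):
    """Raised when an input shape collapses below 1 voxel at some layer."""

    def __init__(self, message: str, layer: str | None = None):
        super().__init__(message)
        self.layer = layer


@dataclass
class NetworkConfig:
    """Architecture hyperparameters of the encoder-decoder.

    Defaults follow the published architecture: encoder filter ladder
    32/64/128/256, a mirrored decoder, 3x3x3 kernels, valid padding, ReLU
    after every convolutional operation, and a single-channel output layer.
    ``final_relu`` additionally rectifies the output layer (DVR is
    non-negative); set it to False for an unconstrained linear output.
    """

    encoder_filters: tuple[int, ...] = (32, 64, 128, 256)
    decoder_filters: tuple[int, ...] = (256, 128, 64, 32)
    kernel: int = 3
    padding_mode: str = "valid"
    activation: str = "relu"
    output_channels: int = 1
    downsample_stride: int = 2
    in_channels: int = 1
    final_relu: bool = True
    init_seed: int = 0

    def __post_init__(self):
        self.encoder_filters = tuple(int(f) for f in self.encoder_filters)
        self.decoder_filters = tuple(int(f) for f in self.decoder_filters)
        if self.decoder_filters != tuple(reversed(self.encoder_filters)):
            raise ValueError(
                "decoder_filters must mirror encoder_filters in reverse; got "
                f"{self.decoder_filters} vs reversed {tuple(reversed(self.encoder_filters))}"
            )
        if self.kernel < 3 or self.kernel % 2 == 0:
            raise ValueError("kernel must be odd and >= 3")
        if self.padding_mode != "valid":
            raise ValueError("only valid padding is supported")
        if self.activation != "relu":
            raise ValueError("only relu activation is supported")
        if self.output_channels != 1:
            raise ValueError("output_channels must be 1 (a single DVR channel)")
        if self.downsample_stride < 1:
            raise ValueError("downsample_stride must be >= 1")
        if any(f < 1 for f in self.encoder_filters):
            raise ValueError("filter counts must be positive")

    def layer_plan(self) -> list[tuple[str, str, int, int, int]]:
        """Per-layer (name, kind, c_in, c_out, stride) for the 2L+1 layers."""
        plan = []
        c_prev = self.in_channels
        for i, f in enumerate(self.encoder_filters):
            plan.append((f"enc{i + 1}", "conv", c_prev, f, self.downsample_stride))
            c_prev = f
        for i, f in enumerate(self.decoder_filters):
            plan.append((f"dec{i + 1}", "tconv", c_prev, f, self.downsample_stride))
            c_prev = f
        plan.append(("out", "conv", c_prev, self.output_channels, 1))
        return plan

    def n_parameters(self) -> int:
        """Closed-form trainable parameter count: sum of k^3*c_in*c_out + c_out."""
        k3 = self.kernel**3
        return sum(k3 * ci * co + co for _, _, ci, co, _ in self.layer_plan())


@dataclass
class ShapeTrace:
    """Per-layer spatial dimensions for one input shape."""

    input_shape: tuple[int, ...]
    steps: list[tuple[str, tuple[int, ...], tuple[int, ...]]] = field(default_factory=list)

    @property
    def output_shape(self) -> tuple[int, ...]:
        return self.steps[-1][2]


def output_shape(cfg: NetworkConfig, input_shape) -> tuple[tuple[int, ...], ShapeTrace]:
    """Valid-padding shape arithmetic through all layers.

    Encoder layers map n -> floor((n - k)/s) + 1, decoder (transposed) layers
    map n -> (n - 1)*s + k, and the stride-1 output layer maps n -> n - k + 1.
    Raises :class:`InadmissibleShapeError`, naming the failing layer, if any
    intermediate dimension would drop below one voxel.
    """
    sp = tuple(int(n) for n in input_shape)
    if len(sp) != 3:
        raise ValueError("input_shape must be 3D")
    trace = ShapeTrace(sp)
    for name, kind, _, _, stride in cfg.layer_plan():
        if kind == "conv":
            if any(n < cfg.kernel for n in sp):
                raise InadmissibleShapeError(
                    f"shape {sp} smaller than kernel {cfg.kernel} at layer {name}", layer=name
                )
            nxt = tuple(conv_out_len(n, cfg.kernel, stride) for n in sp)
        else:
            nxt = tuple(conv_transpose_out_len(n, cfg.kernel, stride) for n in sp)
        if any(n < 1 for n in nxt):
            raise InadmissibleShapeError(f"shape collapses to {nxt} at layer {name}", layer=name)
        trace.steps.append((name, sp, nxt))
        sp = nxt
    return sp, trace


class EncoderDecoder3D:
    """Materialized network: a sequential stack of Conv3D/ConvTranspose3D."""

    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.init_seed)
        self.layers = []
        for name, kind, ci, co, stride in cfg.layer_plan():
            relu = True if name != "out" else cfg.final_relu
            cls = Conv3D if kind == "conv" else ConvTranspose3D
            layer = cls(ci, co, kernel=cfg.kernel, stride=stride, relu=relu, rng=rng)
            layer.name = name
            self.layers.append(layer)

    @property
    def n_parameters(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Map a (N, 1, D, H, W) T1 batch to (N, 1, D', H', W') DVR patches."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None, None]
        elif x.ndim == 4:
            x = x[:, None]
        if x.ndim != 5:
            raise ValueError("input must be 3D, 4D (N,D,H,W) or 5D (N,C,D,H,W)")
        output_shape(self.cfg, x.shape[2:])  # reject inadmissible patches before compute
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    __call__ = forward

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    def params_grads(self):
        for layer in self.layers:
            yield from layer.params_grads()

    def parameters(self):
        return [p for layer in self.layers for p in (layer.W, layer.b)]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"{layer.name}.{nm}": getattr(layer, nm).copy()
                for layer in self.layers for nm in ("W", "b")}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for layer in self.layers:
            for nm in ("W", "b"):
                src = state[f"{layer.name}.{nm}"]
                getattr(layer, nm)[...] = src


def build_network(cfg: NetworkConfig) -> EncoderDecoder3D:
    """Construct the encoder-decoder described by ``cfg``."""
    return EncoderDecoder3D(cfg)
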