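"""Architecture contracts: parameter counts, valid-padding shape arithmetic,
forward correctness against direct-convolution oracles."""

import numpy as np
import pytest
from scipy import signal

from mri2synaptic import (
    InadmissibleShapeError,
    NetworkConfig,
    build_network,
    output_shape,
)
from mri2synaptic.nn import Conv3D, ConvTranspose3D


def closed_form_count(ladder, kernel=3, in_ch=1):
    """Sum of k^3 * c_in * c_out + c_out over the 2L+1 layers."""
    k3 = kernel**3
    total, c = 0, in_ch
    for f in ladder:
        total += k3 * c * f + f
        c = f
    for f in tuple(reversed(ladder)):
        total += k3 * c * f + f
        c = f
    total += k3 * c * 1 + 1
    return total


class TestConfigAndCount:
    def test_first_layer_count_default(self):
        cfg = NetworkConfig()
        first = cfg.layer_plan()[0]
        _, _, ci, co, _ = first
        assert 3**3 * ci * co + co == 896

    @pytest.mark.parametrize("ladder", [(32, 64, 128, 256), (8, 16, 32, 64), (2, 4)])
    def test_parameter_count_closed_form(self, ladder):
        cfg = NetworkConfig(encoder_filters=ladder, decoder_filters=tuple(reversed(ladder)))
        assert cfg.n_parameters() == closed_form_count(ladder)
        # the materialized network reports the same total
        assert build_network(cfg).n_parameters == cfg.n_parameters()

    def test_unmirrored_decoder_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(encoder_filters=(32, 64), decoder_filters=(32, 64))
        with pytest.raises(ValueError):
            NetworkConfig(kernel=4)
        with pytest.raises(ValueError):
            NetworkConfig(output_channels=2)

    def test_count_independent_of_input_shape(self, tiny_net_cfg):
        net = build_network(tiny_net_cfg)
        n0 = net.n_parameters
        net.forward(np.zeros((1, 1, 16, 16, 16), np.float32))
        assert net.n_parameters == n0


class TestShapeArithmetic:
    def test_trace_monotone(self):
        cfg = NetworkConfig()
        _, trace = output_shape(cfg, (64, 64, 64))
        enc = [s for s in trace.steps if s[0].startswith("enc")]
        dec = [s for s in trace.steps if s[0].startswith("dec")]
        for _, before, after in enc:
            assert all(a < b for a, b in zip(after, before))
        for _, before, after in dec:
            assert all(a > b for a, b in zip(after, before))

    def test_inference_patch_admissible_with_small_margin(self):
        """The whole-brain inference patch 240x240x160 passes the valid-
        padding arithmetic and loses at most 8 voxels per axis."""
        out, _ = output_shape(NetworkConfig(), (240, 240, 160))
        assert out == (237, 237, 157)
        assert all(i - o <= 8 for i, o in zip((240, 240, 160), out))

    def test_inadmissible_identifies_layer(self):
        with pytest.raises(InadmissibleShapeError) as err:
            output_shape(NetworkConfig(), (16, 16, 16))
        assert err.value.layer is not None

    def test_forward_matches_output_shape_over_sweep(self):
        """Shape contract: for >= 20 admissible inputs, the realized forward
        output equals the valid-padding arithmetic prediction."""
        cfg = NetworkConfig(encoder_filters=(1, 1, 1, 1), decoder_filters=(1, 1, 1, 1),
                            init_seed=0)
        net = build_network(cfg)
        checked = 0
        for n in range(31, 76):
            try:
                expected, _ = output_shape(cfg, (n, 33, 47))
            except InadmissibleShapeError:
                continue
            y = net.forward(np.zeros((1, 1, n, 33, 47), np.float32))
            assert y.shape[2:] == expected
            checked += 1
        assert checked >= 20

    def test_admissibility_precheck_rejects_before_compute(self, tiny_net_cfg):
        net = build_network(tiny_net_cfg)
        with pytest.raises(InadmissibleShapeError):
            net.forward(np.zeros((1, 1, 4, 4, 4), np.float32))


class TestForward:
    def test_zero_weights_give_zero_output(self, tiny_net_cfg):
        net = build_network(tiny_net_cfg)
        for layer in net.layers:
            layer.W[...] = 0
            layer.b[...] = 0
        y = net.forward(np.random.default_rng(0).normal(size=(1, 1, 19, 19, 19)))
        assert np.all(y == 0)

    def test_deterministic_inference(self, tiny_net_cfg):
        net = build_network(tiny_net_cfg)
        x = np.random.default_rng(1).normal(size=(1, 1, 19, 19, 19)).astype(np.float32)
        np.testing.assert_array_equal(net.forward(x), net.forward(x))

    def test_single_conv_matches_direct_convolution(self):
        """A conv layer equals scipy's direct valid correlation."""
        rng = np.random.default_rng(2)
        conv = Conv3D(2, 3, kernel=3, stride=1, relu=False, rng=rng)
        x = rng.normal(size=(1, 2, 5, 6, 7)).astype(np.float32)
        y = conv.forward(x)
        for o in range(3):
            ref = sum(
                signal.correlate(x[0, i].astype(np.float64), conv.W[o, i].astype(np.float64),
                                 mode="valid")
                for i in range(2)
            ) + conv.b[o]
            np.testing.assert_allclose(y[0, o], ref, atol=1e-5)

    def test_transposed_conv_matches_zero_stuffed_convolution(self):
        """Transposed conv with stride s equals zero-stuffing the input then
        full convolution with the (un-flipped) kernel."""
        rng = np.random.default_rng(3)
        tconv = ConvTranspose3D(1, 1, kernel=3, stride=2, relu=False, rng=rng)
        x = rng.normal(size=(1, 1, 3, 3, 3)).astype(np.float32)
        y = tconv.forward(x)
        stuffed = np.zeros((5, 5, 5))
        stuffed[::2, ::2, ::2] = x[0, 0]
        ref = signal.convolve(stuffed, tconv.W[0, 0].astype(np.float64), mode="full")
        np.testing.assert_allclose(y[0, 0], ref + tconv.b[0], atol=1e-5)

    def test_relu_output_nonnegative(self, tiny_net_cfg):
        net = build_network(tiny_net_cfg)
        y = net.forward(np.random.default_rng(4).normal(size=(1, 1, 19, 19, 19)))
        assert y.min() >= 0  # final rectifier: DVR predictions are physical

    def test_translation_covariance_stride1(self):
        """On a stride-1 layer, shifting the input by one voxel shifts the
        valid-region output by one voxel."""
        rng = np.random.default_rng(5)
        conv = Conv3D(1, 1, kernel=3, stride=1, relu=False, rng=rng)
        x = rng.normal(size=(1, 1, 10, 10, 10)).astype(np.float32)
        y = conv.forward(x)
        y_shift = conv.forward(np.roll(x, 1, axis=2))
        np.testing.assert_allclose(y_shift[0, 0, 2:], y[0, 0, 1:-1], atol=1e-6)


class TestGradients:
    @pytest.mark.parametrize("layer_cls,stride", [(Conv3D, 1), (Conv3D, 2),
                                                  (ConvTranspose3D, 2)])
    def test_backward_matches_finite_differences(self, layer_cls, stride):
        rng = np.random.default_rng(6)
        layer = layer_cls(2, 2, kernel=3, stride=stride, relu=False, rng=rng)
        layer.W = layer.W.astype(np.float64)
        layer.b = layer.b.astype(np.float64)
        x = rng.normal(size=(1, 2, 5, 5, 5))

        def loss(inp):
            y = layer.forward(inp, train=True)
            return 0.5 * float((y**2).sum())

        base = loss(x)
        y = layer.forward(x, train=True)
        gx = layer.backward(y)
        eps = 1e-6
        for idx in [(0, 0, 1, 2, 3), (0, 1, 4, 0, 2)]:
            xp = x.copy()
            xp[idx] += eps
            num = (loss(xp) - base) / eps
            assert gx[idx] == pytest.approx(num, rel=1e-4, abs=1e-7)
        widx = (0, 1, 2, 1, 0)
        wsave = layer.W.copy()
        layer.W = wsave.copy()
        layer.W[widx] += eps
        num = (loss(x) - base) / eps
        layer.W = wsave
        layer.forward(x, train=True)
        layer.backward(layer.forward(x, train=True))
        assert layer.gW[widx] == pytest.approx(num, rel=1e-4, abs=1e-7)
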