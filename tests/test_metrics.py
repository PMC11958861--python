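"""Metric correctness against independent brute-force voxel-loop oracles."""

import numpy as np
import pytest
from scipy import stats

from mri2synaptic import metrics as M
from mri2synaptic.metrics import DegenerateRegionError, SSIMParams


def _loop_mse(x, y, m):
    acc, n = 0.0, 0
    for i in np.ndindex(x.shape):
        if m[i]:
            acc += (float(x[i]) - float(y[i])) ** 2
            n += 1
    return acc / n


def _loop_moments(x, y, m):
    xs = [float(x[i]) for i in np.ndindex(x.shape) if m[i]]
    ys = [float(y[i]) for i in np.ndindex(y.shape) if m[i]]
    n = len(xs)
    mx, my = sum(xs) / n, sum(ys) / n
    vx = sum((v - mx) ** 2 for v in xs) / n
    vy = sum((v - my) ** 2 for v in ys) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(xs, ys)) / n
    return mx, my, vx, vy, cov


def _loop_ssim(x, y, m, k1=0.01, k2=0.03):
    mx, my, vx, vy, cov = _loop_moments(x, y, m)
    xs = [float(x[i]) for i in np.ndindex(x.shape) if m[i]]
    L = max(xs) - min(xs) or 1.0
    c1, c2 = (k1 * L) ** 2, (k2 * L) ** 2
    return ((2 * mx * my + c1) * (2 * cov + c2)) / ((mx**2 + my**2 + c1) * (vx + vy + c2))


@pytest.mark.parametrize("trial", range(10))
def test_metrics_match_voxel_loop_oracles(trial):
    """MSE, global SSIM, bias, Pearson and the LS fit agree with explicit
    voxel loops on random 8^3 pairs to relative error < 1e-10."""
    rng = np.random.default_rng(1000 + trial)
    x = rng.uniform(0.1, 2.0, (8, 8, 8))
    y = x + rng.normal(0, 0.3, (8, 8, 8))
    m = rng.uniform(size=(8, 8, 8)) > 0.3

    assert M.mse(x, y, m) == pytest.approx(_loop_mse(x, y, m), rel=1e-10)
    assert M.ssim_global(x, y, m) == pytest.approx(_loop_ssim(x, y, m), rel=1e-10)

    mx, my, vx, vy, cov = _loop_moments(x, y, m)
    assert M.percent_bias(x, y, m) == pytest.approx(100 * (mx - my) / mx, rel=1e-10)
    assert M.pearson(x, y, m) == pytest.approx(cov / np.sqrt(vx * vy), rel=1e-10)

    fit = M.joint_histogram_fit(x, y, m)
    slope = cov / vx
    intercept = my - slope * mx
    assert fit.slope == pytest.approx(slope, rel=1e-10)
    assert fit.intercept == pytest.approx(intercept, rel=1e-8)
    assert fit.rho == pytest.approx(cov / np.sqrt(vx * vy), rel=1e-10)
    assert fit.hist.sum() == m.sum()


def test_metric_trivial_values():
    x = np.arange(27, dtype=float).reshape(3, 3, 3) + 1
    m = np.ones_like(x, bool)
    assert M.mse(x, x, m) == 0.0
    assert M.mse(x, x + 2, m) == pytest.approx(4.0)
    assert M.ssim_global(x, x, m) == pytest.approx(1.0)
    # constants rescue the 0/0 of two identical constant images
    c = np.full((3, 3, 3), 5.0)
    assert M.ssim_global(c, c, m) == pytest.approx(1.0)
    assert M.percent_bias(x, x, m) == 0.0
    assert M.percent_bias(np.full_like(x, 2), np.full_like(x, 1), m) == pytest.approx(50.0)
    assert M.pearson(x, 2 * x + 3, m) == pytest.approx(1.0)
    assert M.pearson(x, -x, m) == pytest.approx(-1.0)
    fit = M.joint_histogram_fit(x, 0.5 * x, m)
    assert fit.slope == pytest.approx(0.5)
    fit = M.joint_histogram_fit(x, x, m)
    assert (fit.slope, fit.intercept) == (pytest.approx(1.0), pytest.approx(0.0, abs=1e-9))


def test_metric_errors():
    x = np.ones((3, 3, 3))
    with pytest.raises(ValueError):
        M.mse(x, np.ones((3, 3, 4)))
    with pytest.raises(DegenerateRegionError):
        M.mse(x, x, np.zeros((3, 3, 3), bool))
    with pytest.raises(DegenerateRegionError):
        M.percent_bias(np.zeros((3, 3, 3)), x)
    with pytest.raises(DegenerateRegionError):
        M.pearson(x, x)
    with pytest.raises(ValueError):
        M.ssim_global(x, np.ones((2, 2, 2)))


def test_ssim_identity_property():
    """ssim(x, x) = 1 for nonconstant x, over many random volumes."""
    rng = np.random.default_rng(7)
    for _ in range(100):
        x = rng.normal(size=(6, 6, 6))
        assert M.ssim_global(x, x) == pytest.approx(1.0, abs=1e-12)


def test_percent_bias_sign_convention():
    """Bias is positive when the prediction undershoots the ground truth."""
    rng = np.random.default_rng(8)
    x = rng.uniform(1, 2, (5, 5, 5))
    assert M.percent_bias(x, 0.9 * x) > 0  # undershoot -> positive
    assert M.percent_bias(x, 1.1 * x) < 0  # overshoot -> negative
    assert M.percent_bias(x, 0.5 * x) == pytest.approx(50.0)


def test_roi_report_locality_and_oracle():
    rng = np.random.default_rng(9)
    x = rng.uniform(0.5, 2.0, (10, 10, 10))
    atlas = np.zeros((10, 10, 10), int)
    atlas[:5] = 1
    atlas[5:, :5] = 2
    atlas[5:, 5:] = 3
    # identical volumes: zero bias, unit ssim everywhere
    rep = M.roi_report(x, x, atlas)
    assert (rep["percent_bias"] == 0).all() and np.allclose(rep["ssim"], 1.0)
    # scaling exactly one ROI moves only that ROI's bias
    y = x.copy()
    y[atlas == 2] *= 0.9
    rep = M.roi_report(x, y, atlas, {1: "a", 2: "b", 3: "c"})
    by = rep.set_index("roi")
    assert by.loc["b", "percent_bias"] == pytest.approx(10.0)
    assert by.loc["a", "percent_bias"] == pytest.approx(0.0, abs=1e-12)
    assert by.loc["c", "percent_bias"] == pytest.approx(0.0, abs=1e-12)
    # every row matches a per-label recomputation
    y = x + rng.normal(0, 0.1, x.shape)
    rep = M.roi_report(x, y, atlas)
    for _, row in rep.iterrows():
        m = atlas == row["label"]
        assert row["percent_bias"] == pytest.approx(M.percent_bias(x, y, m))
        assert row["ssim"] == pytest.approx(M.ssim_global(x, y, m))
    # an absent label is flagged, not dropped
    rep = M.roi_report(x, y, atlas, {1: "a", 2: "b", 3: "c", 9: "ghost"})
    assert bool(rep.set_index("roi").loc["ghost", "empty"])


def test_group_ttest_trivial_and_power():
    rng = np.random.default_rng(10)
    vals = np.r_[np.zeros(5), np.zeros(5)] + 1.0
    groups = np.r_[["a"] * 5, ["b"] * 5]
    t, p = M.group_ttest(vals, groups, "a", "b")
    assert t == pytest.approx(0.0) and p == pytest.approx(1.0)
    # strongly separated groups: p < 0.001 in essentially every draw
    hits = 0
    for _ in range(50):
        vals = np.r_[rng.normal(0, 1, 20), rng.normal(5, 1, 20)]
        groups = np.r_[["a"] * 20, ["b"] * 20]
        _, p = M.group_ttest(vals, groups, "a", "b")
        hits += p < 1e-3
    assert hits >= 49
    with pytest.raises(ValueError):
        M.group_ttest([1.0, 2.0, 3.0], ["a", "a", "b"], "a", "b")


def test_group_ttest_null_calibration():
    """Under the null, Welch p-values are uniform (KS not rejected)."""
    rng = np.random.default_rng(11)
    ps = []
    for _ in range(300):
        vals = rng.normal(0, 1, 40)
        groups = np.r_[["a"] * 20, ["b"] * 20]
        ps.append(M.group_ttest(vals, groups, "a", "b")[1])
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_aggregate_recomputes_exactly():
    import pandas as pd

    rng = np.random.default_rng(12)
    df = pd.DataFrame({
        "diagnosis": ["HC"] * 4 + ["AD"] * 3,
        "mse": rng.uniform(size=7),
        "ssim": rng.uniform(size=7),
    })
    table = M.aggregate_by_group(df, ["mse", "ssim"])
    assert table.loc["HC", ("mse", "mean")] == pytest.approx(df[df.diagnosis == "HC"].mse.mean())
    assert table.loc["AD", ("ssim", "std")] == pytest.approx(df[df.diagnosis == "AD"].ssim.std())
    assert table.loc["All", ("mse", "mean")] == pytest.approx(df.mse.mean())


def test_windowed_ssim_close_to_global_on_smooth_pair():
    """The windowed variant exists for comparison and broadly tracks the
    global form on well-matched smooth images."""
    rng = np.random.default_rng(13)
    from scipy import ndimage

    x = ndimage.gaussian_filter(rng.normal(size=(16, 16, 16)), 2)
    y = x + rng.normal(0, 0.01, x.shape)
    g = M.ssim_global(x, y)
    w = M.ssim_windowed(x, y)
    assert 0.8 < g <= 1.0 and 0.8 < w <= 1.0


class TestMetricProperties:
    """Algebraic invariants checked over generated volumes."""

    from hypothesis import given, settings, strategies as st

    @staticmethod
    def _vol(seed):
        return np.random.default_rng(seed).uniform(0.2, 2.0, (5, 5, 5))

    @given(seed=st.integers(0, 10_000), c=st.floats(0.1, 1.9))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bias_of_scaled_prediction(self, seed, c):
        """percent_bias(x, c*x) = 100*(1 - c) for any positive volume."""
        x = self._vol(seed)
        assert M.percent_bias(x, c * x) == pytest.approx(100 * (1 - c), abs=1e-8)

    @given(seed=st.integers(0, 10_000), a=st.floats(0.5, 3.0), b=st.floats(-1.0, 1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_pearson_affine_invariance(self, seed, a, b):
        """Correlation is invariant to positive affine maps of one argument."""
        x = self._vol(seed)
        y = self._vol(seed + 1)
        assert M.pearson(x, a * y + b) == pytest.approx(M.pearson(x, y), abs=1e-9)
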