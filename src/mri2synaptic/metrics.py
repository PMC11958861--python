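"""Image-quality metrics: MSE, global SSIM, percentage bias, Pearson rho.

All metrics are computed over an explicit evaluation mask (conventionally
the brain mask, since the images are brain-masked upstream) and refuse shape
mismatches rather than broadcasting.

SSIM here is the *global-moment* form

    SSIM = (2 mu_x mu_y + c1)(2 sigma_xy + c2)
           / ((mu_x^2 + mu_y^2 + c1)(sigma_x^2 + sigma_y^2 + c2))

computed from a single set of masked means/variances/covariance, with
c1 = (k1 L)^2, c2 = (k2 L)^2 and L the dynamic range of the ground truth
within the mask.  A sliding-window variant is available behind a flag for
comparison with the conventional local SSIM.

Percentage bias is signed, ground truth minus prediction over ground truth,
reported in percent: negative when the prediction overshoots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .volume import Volume


class DegenerateRegionError(ValueError):
    """A metric's region is empty or its reference mean is zero."""


def _vals(v) -> np.ndarray:
    return v.values if isinstance(v, Volume) else np.asarray(v)


def _masked_pair(x, y, mask):
    xv, yv = _vals(x), _vals(y)
    if xv.shape != yv.shape:
        raise ValueError(f"shape mismatch: {xv.shape} vs {yv.shape}")
    if mask is None:
        m = np.ones(xv.shape, dtype=bool)
    else:
        m = _vals(mask).astype(bool)
        if m.shape != xv.shape:
            raise ValueError(f"mask shape {m.shape} does not match volumes {xv.shape}")
    if not m.any():
        raise DegenerateRegionError("evaluation mask is empty")
    return xv[m].astype(np.float64), yv[m].astype(np.float64)


@dataclass
class SSIMParams:
    """Regularization constants of the global SSIM.

    c1 = (k1 L)^2 and c2 = (k2 L)^2 with L the dynamic range of the ground
    truth within the evaluation mask (or supplied explicitly).
    """

    k1: float = 0.01
    k2: float = 0.03
    L: float | None = None

    def constants(self, x_masked: np.ndarray) -> tuple[float, float]:
        L = self.L
        if L is None:
            L = float(x_masked.max() - x_masked.min())
            if L == 0.0:
                L = 1.0  # degenerate constant image; keep c1, c2 > 0
        c1 = (self.k1 * L) ** 2
        c2 = (self.k2 * L) ** 2
        if c1 <= 0 or c2 <= 0:
            raise ValueError("SSIM constants must be positive")
        return c1, c2


def mse(x, y, mask=None) -> float:
    """Mean squared difference over the mask (n = mask voxel count)."""
    xv, yv = _masked_pair(x, y, mask)
    return float(np.mean((xv - yv) ** 2))


def ssim_global(x, y, mask=None, params: SSIMParams | None = None) -> float:
    """Single global-moment SSIM over the masked voxels."""
    xv, yv = _masked_pair(x, y, mask)
    params = params or SSIMParams()
    c1, c2 = params.constants(xv)
    mx, my = xv.mean(), yv.mean()
    vx, vy = xv.var(), yv.var()
    cov = ((xv - mx) * (yv - my)).mean()
    return float(
        ((2 * mx * my + c1) * (2 * cov + c2))
        / ((mx**2 + my**2 + c1) * (vx + vy + c2))
    )


def ssim_windowed(x, y, mask=None, params: SSIMParams | None = None,
                  sigma: float = 1.5) -> float:
    """Gaussian-window SSIM averaged within the mask (comparison variant)."""
    from skimage.metrics import structural_similarity

    xv, yv = _vals(x).astype(np.float64), _vals(y).astype(np.float64)
    if xv.shape != yv.shape:
        raise ValueError(f"shape mismatch: {xv.shape} vs {yv.shape}")
    params = params or SSIMParams()
    m = np.ones(xv.shape, bool) if mask is None else _vals(mask).astype(bool)
    if not m.any():
        raise DegenerateRegionError("evaluation mask is empty")
    L = params.L or float(xv[m].max() - xv[m].min()) or 1.0
    _, smap = structural_similarity(
        xv, yv, data_range=L, gaussian_weights=True, sigma=sigma,
        use_sample_covariance=False, K1=params.k1, K2=params.k2, full=True,
    )
    return float(smap[m].mean())


def percent_bias(x, y, region_mask=None) -> float:
    """100 * (mean_x(R) - mean_y(R)) / mean_x(R) over region R."""
    xv, yv = _masked_pair(x, y, region_mask)
    mx = xv.mean()
    if mx == 0.0:
        raise DegenerateRegionError("ground-truth region mean is zero")
    return float(100.0 * (mx - yv.mean()) / mx)


def pearson(x, y, mask=None) -> float:
    """Sample Pearson correlation over masked voxels."""
    xv, yv = _masked_pair(x, y, mask)
    if xv.std() == 0.0 or yv.std() == 0.0:
        raise DegenerateRegionError("correlation undefined for a constant input")
    return float(np.corrcoef(xv, yv)[0, 1])


@dataclass
class JointHistogramFit:
    slope: float
    intercept: float
    rho: float
    hist: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray


def joint_histogram_fit(x, y, mask=None, bins: int = 100) -> JointHistogramFit:
    """2D voxel-value histogram plus the least-squares line of y on x."""
    xv, yv = _masked_pair(x, y, mask)
    if xv.std() == 0.0:
        raise DegenerateRegionError("least-squares fit undefined for constant x")
    slope, intercept = np.polyfit(xv, yv, 1)
    hist, xe, ye = np.histogram2d(xv, yv, bins=bins)
    return JointHistogramFit(float(slope), float(intercept), pearson(xv, yv), hist, xe, ye)


def roi_report(x, y, atlas, roi_names: dict[int, str] | None = None,
               ssim_params: SSIMParams | None = None) -> pd.DataFrame:
    """Per-ROI percentage bias and SSIM.

    One row per positive atlas label; an empty ROI yields a flagged row with
    NaN metrics rather than being dropped.
    """
    xv, yv, av = _vals(x), _vals(y), _vals(atlas)
    if not (xv.shape == yv.shape == av.shape):
        raise ValueError("volumes and atlas must share a grid")
    labels = [int(l) for l in np.unique(av) if l > 0]
    if roi_names:
        labels = sorted(set(labels) | set(roi_names))
    rows = []
    for label in labels:
        m = av == label
        name = (roi_names or {}).get(label, f"roi_{label}")
        if not m.any():
            rows.append({"label": label, "roi": name, "n_voxels": 0,
                         "percent_bias": np.nan, "ssim": np.nan, "empty": True})
            continue
        rows.append({
            "label": label,
            "roi": name,
            "n_voxels": int(m.sum()),
            "percent_bias": percent_bias(xv, yv, m),
            "ssim": ssim_global(xv, yv, m, ssim_params),
            "empty": False,
        })
    return pd.DataFrame(rows)


def group_ttest(values, groups, group_a: str, group_b: str,
                equal_var: bool = False) -> tuple[float, float]:
    """Two-sample t-test (Welch by default) between two named groups.

    ``values`` are per-participant ROI means; ``groups`` the matching
    diagnosis labels.  Returns (t statistic, two-sided p).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    a = values[groups == group_a]
    b = values[groups == group_b]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"need >= 2 participants per group, got {len(a)} {group_a} / {len(b)} {group_b}"
        )
    if a.var() == 0.0 and b.var() == 0.0 and a.mean() == b.mean():
        return 0.0, 1.0  # identical degenerate groups: no evidence of difference
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def aggregate_by_group(df: pd.DataFrame, value_cols, group_col: str = "diagnosis"
                       ) -> pd.DataFrame:
    """Group mean +/- SD table recomputed exactly from per-participant rows."""
    value_cols = list(value_cols)
    out = df.groupby(group_col)[value_cols].agg(["mean", "std"])
    overall = df[value_cols].agg(["mean", "std"]).T.stack()
    out.loc["All"] = overall.values
    return out
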