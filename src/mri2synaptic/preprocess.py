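"""Deterministic data preparation: brain masking, resampling, DVR.

The distribution volume ratio is computed from the non-displaceable binding
potential image as DVR = (BP_ND + 1) / (mean BP_ND over the reference region
+ 1), with an integer-label atlas supplying the cerebellum-analog reference
region, so DVR averages to 1 over the reference tissue by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import Volume, require_same_grid


class EmptyReferenceRegionError(ValueError):
    """The reference label selects no voxels in the atlas."""


@dataclass
class DVRInputs:
    """BP_ND volume plus the atlas and label defining the reference region."""

    bpnd: Volume
    atlas: Volume
    reference_label: int


def combine_brain_mask(gm: Volume, wm: Volume, csf: Volume, threshold: float = 0.5) -> Volume:
    """Binary brain mask where summed tissue probability exceeds ``threshold``.

    Mirrors the conventional construction from GM/WM/CSF probability
    segments; the default 0.5 keeps voxels that are at least half tissue.
    """
    require_same_grid(gm, wm, csf)
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    total = gm.values.astype(np.float64) + wm.values + csf.values
    return Volume((total > threshold).astype(np.uint8), gm.voxel_size)


def resample_to_grid(v: Volume, target_voxel_size, target_shape, order: int = 1) -> Volume:
    """Resample onto a new grid by nearest (order 0) or trilinear (order 1).

    Voxel centers sit at world = (index + 1/2) * voxel_size; both grids share
    the world origin at the corner of voxel (0,0,0), so world-space extent is
    preserved up to the half-voxel discretization of each grid.
    """
    if order not in (0, 1):
        raise ValueError("order must be 0 (nearest, labels) or 1 (trilinear, intensities)")
    target_shape = tuple(int(n) for n in target_shape)
    target_voxel_size = tuple(float(s) for s in target_voxel_size)
    if any(n <= 0 for n in target_shape) or any(s <= 0 for s in target_voxel_size):
        raise ValueError("target shape and voxel size must be positive")
    coords = np.meshgrid(
        *[
            ((np.arange(n) + 0.5) * tvs) / svs - 0.5
            for n, tvs, svs in zip(target_shape, target_voxel_size, v.voxel_size)
        ],
        indexing="ij",
    )
    out = ndimage.map_coordinates(
        v.values.astype(np.float64 if order else v.values.dtype),
        np.stack(coords), order=order, mode="nearest",
    )
    if order == 1 and np.issubdtype(v.values.dtype, np.floating):
        out = out.astype(v.values.dtype)
    return Volume(out, target_voxel_size)


def compute_dvr(inputs: DVRInputs) -> Volume:
    """DVR = (BP_ND + 1) / (mean BP_ND over the reference region + 1)."""
    require_same_grid(inputs.bpnd, inputs.atlas)
    ref = inputs.atlas.values == inputs.reference_label
    if not ref.any():
        raise EmptyReferenceRegionError(
            f"reference label {inputs.reference_label} has no voxels in the atlas"
        )
    ref_mean = float(inputs.bpnd.values[ref].mean())
    dvr = (inputs.bpnd.values.astype(np.float64) + 1.0) / (ref_mean + 1.0)
    return Volume(dvr.astype(np.float32), inputs.bpnd.voxel_size)


def apply_mask(v: Volume, mask: Volume) -> Volume:
    """Zero values outside the mask; inside unchanged."""
    require_same_grid(v, mask)
    return Volume(np.where(mask.values > 0, v.values, np.zeros((), dtype=v.values.dtype)),
                  v.voxel_size)
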