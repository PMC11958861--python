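"""Volume container and NIfTI I/O.

A :class:`Volume` is a 3D scalar grid with isotropic-or-not voxel spacing in
mm.  Phantoms are generated axis-aligned, so the world transform is the
diagonal scaling ``world = index * voxel_size`` and no orientation matrix is
carried.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np


@dataclass
class Volume:
    """3D scalar grid with voxel spacing in mm."""

    values: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got ndim={self.values.ndim}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive floats, got {self.voxel_size}")
        if np.issubdtype(self.values.dtype, np.floating) and not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size
        return aff

    def same_grid(self, other: "Volume") -> bool:
        return self.shape == other.shape and np.allclose(self.voxel_size, other.voxel_size)

    def copy(self, values: np.ndarray | None = None) -> "Volume":
        vals = self.values.copy() if values is None else np.asarray(values)
        return Volume(vals, self.voxel_size)

    def save(self, path) -> None:
        """Write as NIfTI (.nii or .nii.gz); dtype is preserved."""
        img = nib.Nifti1Image(self.values, self.affine)
        img.header.set_data_dtype(self.values.dtype)
        img.header.set_zooms(self.voxel_size)
        nib.save(img, str(path))

    @classmethod
    def load(cls, path) -> "Volume":
        img = nib.load(str(path))
        values = np.asanyarray(img.dataobj).astype(img.header.get_data_dtype())
        return cls(values, tuple(float(z) for z in img.header.get_zooms()[:3]))


def require_same_grid(*volumes: Volume) -> None:
    """Raise ValueError unless all volumes share shape and voxel size."""
    first = volumes[0]
    for v in volumes[1:]:
        if not first.same_grid(v):
            raise ValueError(
                f"grid mismatch: {first.shape}@{first.voxel_size} vs {v.shape}@{v.voxel_size}"
            )
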