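"""Labeled voxel images of the left ventricle (0 background, 1 cavity, 2 wall)."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = ["LabelImage"]


@dataclass
class LabelImage:
    """3-D label image with isotropic axes in mm.

    ``voxels`` holds integer labels {0, 1, 2}; ``spacing`` is mm per axis and
    ``origin`` the position (mm) of the corner of voxel (0, 0, 0) — voxel
    centers sit at ``origin + (index + 0.5) * spacing``.
    """

    voxels: np.ndarray
    spacing: np.ndarray = dataclasses.field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = dataclasses.field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.spacing = np.broadcast_to(
            np.asarray(self.spacing, dtype=float), (3,)
        ).copy()
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D array")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")
        bad = ~np.isin(self.voxels, (0, 1, 2))
        if bad.any():
            raise ValueError("labels must be in {0, 1, 2}")

    # ------------------------------------------------------------------
    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def label_volume(self, label: int) -> float:
        """Total volume (ml) of one label class."""
        return int(np.count_nonzero(self.voxels == label)) * self.voxel_volume / 1000.0

    def voxel_centers(self) -> np.ndarray:
        """Coordinates (mm) of all voxel centers, shape (*grid, 3)."""
        axes = [
            self.origin[i] + (np.arange(self.voxels.shape[i]) + 0.5) * self.spacing[i]
            for i in range(3)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)

    def same_grid(self, other: "LabelImage") -> bool:
        return (
            self.voxels.shape == other.voxels.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    # ------------------------------------------------------------------
    def to_nifti(self, path: str) -> None:
        affine = np.eye(4)
        affine[:3, :3] = np.diag(self.spacing)
        affine[:3, 3] = self.origin + 0.5 * self.spacing
        nib.save(nib.Nifti1Image(self.voxels.astype(np.uint8), affine), path)

    @classmethod
    def from_nifti(cls, path: str) -> "LabelImage":
        img = nib.load(path)
        data = np.asarray(img.dataobj).astype(np.uint8)
        affine = img.affine
        spacing = np.abs(np.diag(affine)[:3])
        origin = affine[:3, 3] - 0.5 * spacing
        return cls(voxels=data, spacing=spacing, origin=origin)
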