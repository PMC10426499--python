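"""Shared data structures."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AXIS_NAMES = ("x", "y", "z")  # array axis 0 = x (medial-lateral), 1 = y (antero-posterior)


@dataclass
class VolumeWithMask:
    """A 3D intensity volume (HU), its voxel spacing (mm per axis) and an
    aligned binary ROI mask.

    Array axis order is (x, y, z); ``spacing[i]`` is the physical size of a
    voxel along array axis ``i``.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float]
    mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        self.mask = np.asarray(self.mask).astype(bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array")
        if self.mask.shape != self.intensities.shape:
            raise ValueError("mask and intensities must share a shape")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive lengths (mm)")
        if not self.mask.any():
            raise ValueError("mask must contain at least one foreground voxel")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def mask_bounding_box(self) -> list[tuple[int, int]]:
        """Inclusive (lo, hi) voxel index range of the foreground per axis."""
        out = []
        for ax in range(3):
            proj = self.mask.any(axis=tuple(a for a in range(3) if a != ax))
            idx = np.flatnonzero(proj)
            out.append((int(idx[0]), int(idx[-1])))
        return out

    def copy(self) -> "VolumeWithMask":
        return VolumeWithMask(self.intensities.copy(), self.spacing, self.mask.copy())


class DegenerateFeatureError(ValueError):
    """Raised when a statistic is undefined because of zero variance."""
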