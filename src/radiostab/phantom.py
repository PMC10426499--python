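"""Synthetic phantom cohorts: textured ellipsoid shells with labels.

Each subject is a smoothed Gaussian random field inside a hollow
ellipsoidal shell (mimicking a ventricular wall), surrounded by a bright
cavity (contrast-filled pool) and a dark background.  The two classes
differ in the texture statistics inside the shell (mean, SD, correlation
length) and, optionally, in wall thickness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from radiostab.core import VolumeWithMask

# Minimum clearance between the mask bounding box and the volume edge,
# as a fraction of the bounding-box side, so +/-30% translations fit.
PAD_FRACTION = 0.35


@dataclass
class ClassParams:
    """Texture statistics of one class inside the shell."""

    mean_hu: float = 200.0
    sd_hu: float = 20.0
    correlation_length_mm: float = 1.5
    #: SD of the per-subject random offset added to ``mean_hu`` (between-
    #: subject variability; gives the ICC a between-subject variance term).
    subject_mean_sd_hu: float = 25.0
    #: added to the outer semi-axes (mm); models mild shape differences
    wall_thickness_delta_mm: float = 0.0


@dataclass
class PhantomConfig:
    n_subjects_per_class: int = 5
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    outer_semi_axes_mm: tuple[float, float, float] = (28.0, 26.0, 24.0)
    inner_semi_axes_mm: tuple[float, float, float] = (16.0, 15.0, 14.0)
    class_params: tuple[ClassParams, ClassParams] = field(
        default_factory=lambda: (
            ClassParams(correlation_length_mm=1.5, sd_hu=20.0),
            ClassParams(correlation_length_mm=4.0, sd_hu=35.0),
        )
    )
    #: cavity (inside the inner ellipsoid) intensity range, drawn per subject
    cavity_hu_range: tuple[float, float] = (380.0, 520.0)
    #: background (outside the outer ellipsoid) intensity range, per subject
    background_hu_range: tuple[float, float] = (-80.0, 20.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_class < 2:
            raise ValueError("each class needs n >= 2 subjects")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")
        if not all(i < o for i, o in zip(self.inner_semi_axes_mm, self.outer_semi_axes_mm)):
            raise ValueError("inner semi-axes must be strictly smaller than outer")


def _ellipsoid(shape, spacing, center_mm, semi_axes_mm) -> np.ndarray:
    grids = np.meshgrid(
        *(np.arange(n) * s for n, s in zip(shape, spacing)), indexing="ij", sparse=True
    )
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center_mm, semi_axes_mm))
    return q <= 1.0


def _smooth_unit_field(rng: np.random.Generator, shape, spacing, corr_len_mm) -> np.ndarray:
    """White noise filtered to the requested correlation length, re-scaled to
    unit variance."""
    noise = rng.standard_normal(shape)
    sigma_vox = [max(corr_len_mm / s, 1e-6) / 2.0 for s in spacing]
    f = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="wrap")
    sd = f.std()
    if sd < 1e-12:  # pragma: no cover - needs a pathological kernel
        raise ValueError("texture field collapsed to a constant")
    return f / sd


def shell_masks(config: PhantomConfig, outer_semi_axes=None):
    """Outer ellipsoid, inner ellipsoid and shell mask for a config."""
    shape = tuple(config.grid_shape)
    spacing = tuple(config.voxel_spacing)
    center = [((n - 1) * s) / 2.0 for n, s in zip(shape, spacing)]
    outer_ax = outer_semi_axes if outer_semi_axes is not None else config.outer_semi_axes_mm
    outer = _ellipsoid(shape, spacing, center, outer_ax)
    inner = _ellipsoid(shape, spacing, center, config.inner_semi_axes_mm)
    shell = outer & ~inner
    return outer, inner, shell


def analytic_shell_volume_mm3(config: PhantomConfig) -> float:
    a = np.prod(config.outer_semi_axes_mm)
    b = np.prod(config.inner_semi_axes_mm)
    return float(4.0 / 3.0 * np.pi * (a - b))


def _check_padding(mask: np.ndarray) -> None:
    for ax in range(3):
        proj = mask.any(axis=tuple(a for a in range(3) if a != ax))
        idx = np.flatnonzero(proj)
        lo, hi = int(idx[0]), int(idx[-1])
        box = hi - lo + 1
        margin = min(lo, mask.shape[ax] - 1 - hi)
        if margin < PAD_FRACTION * box:
            raise ValueError(
                f"mask too close to the volume edge along axis {ax}: "
                f"margin {margin} voxels < {PAD_FRACTION:.0%} of box ({box} voxels); "
                "enlarge grid_shape or shrink the ellipsoid"
            )


def generate_subject(
    config: PhantomConfig, label: int, rng: np.random.Generator
) -> VolumeWithMask:
    """One textured shell subject of class ``label`` (0 or 1)."""
    params = config.class_params[label]
    outer_ax = tuple(
        a + params.wall_thickness_delta_mm for a in config.outer_semi_axes_mm
    )
    outer, inner, shell = shell_masks(config, outer_semi_axes=outer_ax)
    if not shell.any():
        raise ValueError("geometry yields an empty shell ROI")
    _check_padding(shell)

    spacing = tuple(config.voxel_spacing)
    field = _smooth_unit_field(rng, config.grid_shape, spacing, params.correlation_length_mm)
    subject_mean = params.mean_hu + rng.normal(0.0, params.subject_mean_sd_hu)
    wall = subject_mean + params.sd_hu * field

    cavity_hu = rng.uniform(*config.cavity_hu_range)
    background_hu = rng.uniform(*config.background_hu_range)
    ambient_noise = 5.0 * rng.standard_normal(config.grid_shape)

    vol = np.where(inner, cavity_hu, background_hu) + ambient_noise
    vol[shell] = wall[shell]
    return VolumeWithMask(vol, spacing, shell)


def generate_cohort(config: PhantomConfig) -> list[tuple[VolumeWithMask, int]]:
    """Full two-class cohort: ``2 * n_subjects_per_class`` labelled subjects.

    Deterministic for a fixed config (seed included).  Subjects are ordered
    class 0 first, then class 1.
    """
    rng = np.random.default_rng(config.seed)
    cohort: list[tuple[VolumeWithMask, int]] = []
    for label in (0, 1):
        for _ in range(config.n_subjects_per_class):
            cohort.append((generate_subject(config, label, rng), label))
    return cohort
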