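"""Denoising and resampling to a common isotropic geometry.

Order is fixed: denoise first (truncated discrete Gaussian on the native
grid), then resample image and mask to the target spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from radiostab.core import VolumeWithMask


@dataclass
class PreprocessConfig:
    gaussian_kernel: tuple[int, int, int] = (3, 3, 3)
    gaussian_sigma: float = 0.5
    target_spacing: float = 2.0
    image_spline_order: int = 3
    # mask is resampled with nearest-neighbour so labels stay binary
    mask_spline_order: int = 0

    def __post_init__(self) -> None:
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be > 0")
        if self.target_spacing <= 0:
            raise ValueError("target_spacing must be > 0")
        if any(k < 1 or k % 2 == 0 for k in self.gaussian_kernel):
            raise ValueError("kernel sides must be odd and >= 1")


def gaussian_kernel_3d(kernel: tuple[int, int, int], sigma: float) -> np.ndarray:
    """Separable discrete Gaussian truncated to ``kernel`` support,
    renormalized to unit sum."""
    axes = []
    for k in kernel:
        r = k // 2
        x = np.arange(-r, r + 1, dtype=np.float64)
        w = np.exp(-(x**2) / (2.0 * sigma**2))
        axes.append(w)
    ker = axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
    return ker / ker.sum()


def denoise(v: VolumeWithMask, cfg: PreprocessConfig | None = None) -> VolumeWithMask:
    """Smooth intensities with the truncated Gaussian; mask is untouched."""
    cfg = cfg or PreprocessConfig()
    if any(n < k for n, k in zip(v.shape, cfg.gaussian_kernel)):
        raise ValueError("volume smaller than the smoothing kernel")
    ker = gaussian_kernel_3d(cfg.gaussian_kernel, cfg.gaussian_sigma)
    smoothed = ndimage.correlate(v.intensities, ker, mode="nearest")
    return VolumeWithMask(smoothed, v.spacing, v.mask)


def resample(v: VolumeWithMask, cfg: PreprocessConfig | None = None) -> VolumeWithMask:
    """Resample to isotropic ``target_spacing``: B-spline for the image,
    nearest-neighbour for the mask (stays exactly binary)."""
    cfg = cfg or PreprocessConfig()
    target = float(cfg.target_spacing)
    zoom = [s / target for s in v.spacing]
    if np.allclose(zoom, 1.0):
        return v.copy()
    img = ndimage.zoom(
        v.intensities, zoom, order=cfg.image_spline_order, mode="nearest", grid_mode=True
    )
    mask = ndimage.zoom(
        v.mask.astype(np.uint8), zoom, order=cfg.mask_spline_order,
        mode="nearest", grid_mode=True,
    ).astype(bool)
    if not mask.any():
        raise ValueError("resampling removed all foreground voxels")
    return VolumeWithMask(img, (target, target, target), mask)


def preprocess(v: VolumeWithMask, cfg: PreprocessConfig | None = None) -> VolumeWithMask:
    """denoise -> resample."""
    cfg = cfg or PreprocessConfig()
    return resample(denoise(v, cfg), cfg)
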