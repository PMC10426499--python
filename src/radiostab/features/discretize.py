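"""Fixed-bin-width gray-level discretization."""

from __future__ import annotations

import numpy as np


def discretize_fixed_bin_width(values: np.ndarray, bin_width: float) -> np.ndarray:
    """Map intensities to integer gray levels 1..Ng with a fixed bin width.

    level(x) = floor(x / w) - floor(min / w) + 1, so bins are anchored to
    multiples of the bin width and the lowest occupied level is 1.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    v = np.asarray(values, dtype=np.float64)
    low = np.floor(v.min() / bin_width)
    return (np.floor(v / bin_width) - low + 1).astype(np.int64)


def discretize_volume(
    intensities: np.ndarray, mask: np.ndarray, bin_width: float
) -> tuple[np.ndarray, int]:
    """Discretize a masked volume; voxels outside the mask get level 0.

    Returns the level volume and the number of gray levels Ng (max level).
    """
    disc = np.zeros(intensities.shape, dtype=np.int64)
    disc[mask] = discretize_fixed_bin_width(intensities[mask], bin_width)
    return disc, int(disc.max())
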