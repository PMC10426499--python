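"""First-order intensity statistics (18 features).

Definitions follow the IBSI nomenclature; Entropy and Uniformity are
computed on the fixed-bin-width discretized histogram, everything else on
the raw HU values inside the ROI.
"""

from __future__ import annotations

import numpy as np

FIRST_ORDER_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


def first_order_features(
    values: np.ndarray, disc: np.ndarray, voxel_volume: float
) -> dict[str, float]:
    """18 first-order statistics of the ROI.

    ``values``: raw HU values inside the ROI; ``disc``: matching discretized
    gray levels (1..Ng); ``voxel_volume``: mm^3 per voxel.
    """
    x = np.asarray(values, dtype=np.float64)
    n = x.size
    if n < 1:
        raise ValueError("empty ROI")

    counts = np.bincount(np.asarray(disc, dtype=np.int64))[1:]
    p = counts[counts > 0] / n

    mean = float(x.mean())
    var = float(x.var())  # population variance
    sd = np.sqrt(var)
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    inner = x[(x >= p10) & (x <= p90)]

    if sd > 0:
        z = (x - mean) / sd
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4))  # not excess kurtosis
    else:
        skew, kurt = 0.0, 0.0

    energy = float(np.sum(x**2))
    return {
        "Energy": energy,
        "TotalEnergy": voxel_volume * energy,
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RobustMeanAbsoluteDeviation": (
            float(np.mean(np.abs(inner - inner.mean()))) if inner.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float(np.sum(p**2)),
    }
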