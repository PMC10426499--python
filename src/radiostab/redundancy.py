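"""Redundancy removal by absolute Spearman correlation.

When two features correlate above the threshold, the one with the lower
mean absolute correlation against the remaining features is kept.  The
greedy order is highest-offending-pair first; ties are broken by
lexicographic feature name for reproducibility.  A threshold of 1 removes
nothing (|rho| > 1 is impossible).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CANDIDATE_THRESHOLDS = (0.80, 0.85, 0.90, 0.95, 1.0)


@dataclass
class CorrelationFilterConfig:
    threshold: float = 0.95

    def __post_init__(self) -> None:
        if not (0 < self.threshold <= 1):
            raise ValueError("threshold must be in (0, 1]")


def spearman_abs_matrix(data: pd.DataFrame) -> pd.DataFrame:
    """|Spearman rho| between all feature pairs; constant features get 0
    correlation with everything (rho undefined), with a logged warning."""
    X = data.to_numpy(dtype=np.float64)
    const = np.ptp(X, axis=0) == 0
    if const.any():
        logger.info(
            "constant features treated as correlation 0: %s",
            list(data.columns[const]),
        )
    if X.shape[1] == 1:
        rho = np.ones((1, 1))
    else:
        ranks = stats.rankdata(X, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.corrcoef(ranks, rowvar=False)
    rho = np.abs(np.nan_to_num(rho, nan=0.0))
    np.fill_diagonal(rho, 1.0)
    rho[const, :] = 0.0
    rho[:, const] = 0.0
    return pd.DataFrame(rho, index=data.columns, columns=data.columns)


def correlation_filter(
    data: pd.DataFrame, cfg: CorrelationFilterConfig | float = 0.95
) -> list[str]:
    """Retained feature names after greedy decorrelation.

    ``data``: subjects x features values (labels not used).
    """
    if isinstance(cfg, (int, float)):
        cfg = CorrelationFilterConfig(float(cfg))
    if len(data) < 2:
        raise ValueError("need at least 2 subjects")

    corr = spearman_abs_matrix(data)
    retained = sorted(data.columns)
    C = corr.loc[retained, retained].to_numpy().copy()
    names = list(retained)

    while len(names) > 1:
        A = C.copy()
        np.fill_diagonal(A, 0.0)
        m = A.max()
        if m <= cfg.threshold:
            break
        # all index pairs attaining the max; pick lexicographically first
        cand = np.argwhere(np.isclose(A, m))
        cand = [(i, j) for i, j in cand if i < j]
        i, j = min(cand, key=lambda ij: (names[ij[0]], names[ij[1]]))

        others = [k for k in range(len(names)) if k not in (i, j)]
        if others:
            mean_i = A[i, others].mean()
            mean_j = A[j, others].mean()
        else:
            mean_i = mean_j = 0.0
        if np.isclose(mean_i, mean_j):
            drop = max(i, j, key=lambda k: names[k])  # keep the lexicographic smaller
        elif mean_i > mean_j:
            drop = i
        else:
            drop = j
        keep_idx = [k for k in range(len(names)) if k != drop]
        C = C[np.ix_(keep_idx, keep_idx)]
        names = [names[k] for k in keep_idx]

    return [c for c in data.columns if c in set(names)]
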