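"""Per-class doubling via SMOTE-style neighbour interpolation.

For each class with n_c members, exactly n_c synthetic samples are
generated: every original sample picks one of its Q nearest same-class
neighbours uniformly at random and a new point is placed uniformly at
random on the connecting segment.  The output is originals + synthetics,
so the training set doubles and the class ratio is preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)


@dataclass
class SmoteConfig:
    q_neighbors: int = 5
    seed: int = 0
    target_multiplier: int = 2  # fixed by the procedure: output = 2x input

    def __post_init__(self) -> None:
        if self.q_neighbors < 1:
            raise ValueError("q_neighbors must be >= 1")


def smote_augment(
    data: pd.DataFrame, labels: pd.Series, cfg: SmoteConfig | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Double the training set; synthetics carry their parent's label and an
    id suffixed ``_syn``.  Euclidean metric (inputs are z-scored upstream)."""
    cfg = cfg or SmoteConfig()
    labels = labels.reindex(data.index)
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError("exactly two classes required")

    rng = np.random.default_rng(cfg.seed)
    syn_rows, syn_ids, syn_labels = [], [], []
    for c in classes:
        members = data[labels == c]
        n_c = len(members)
        if n_c < 2:
            raise ValueError(f"class {c} has fewer than 2 members; SMOTE undefined")
        q = cfg.q_neighbors
        if n_c <= q:
            q = n_c - 1
            logger.warning(
                "class %s has %d members; reducing Q from %d to %d",
                c, n_c, cfg.q_neighbors, q,
            )
        X = members.to_numpy(dtype=np.float64)
        D = cdist(X, X)
        np.fill_diagonal(D, np.inf)
        order = np.argsort(D, axis=1, kind="stable")[:, :q]
        for i, sid in enumerate(members.index):
            j = order[i, rng.integers(q)]
            gamma = rng.uniform()
            syn_rows.append(X[i] + gamma * (X[j] - X[i]))
            syn_ids.append(f"{sid}_syn")
            syn_labels.append(c)

    syn = pd.DataFrame(np.array(syn_rows), index=syn_ids, columns=data.columns)
    out_data = pd.concat([data, syn])
    out_labels = pd.concat([labels, pd.Series(syn_labels, index=syn_ids)]).astype(int)
    assert len(out_data) == 2 * len(data)
    return out_data, out_labels
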