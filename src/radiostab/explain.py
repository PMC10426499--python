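"""Model explanation: exact Shapley attributions and PC class attribution.

Shapley values use the interventional value function
``v(S) = E_b[f(x_S, b_{~S})]`` with the expectation over a background set;
for the model's low-dimensional PC inputs all 2^d coalitions are
enumerated, so the attributions are exact (additivity, dummy and symmetry
hold to numerical tolerance).

Principal components are attributed to radiomic feature classes by
squaring their loadings, keeping the squared values above half the PC's
maximum, and summing the kept values per class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from math import factorial
from pathlib import Path

import numpy as np
import pandas as pd

MAX_EXACT_DIM = 16

CLASS_ORDER = ("shape-size", "first-order", "textural")


def _decision_function(model):
    if hasattr(model, "decision_function"):
        return lambda X: np.asarray(model.decision_function(X), dtype=np.float64)
    if hasattr(model, "predict_proba"):
        return lambda X: np.asarray(model.predict_proba(X))[:, 1]
    raise ValueError("model exposes neither decision_function nor predict_proba")


def exact_shapley(
    predict_fn, background: np.ndarray, instances: np.ndarray
) -> tuple[np.ndarray, float]:
    """Exact Shapley attributions of ``predict_fn`` over the feature columns.

    Returns ``(phi, base)`` with ``phi`` of shape (n_instances, d) and
    ``base = E_b[f(b)]``; per instance ``base + phi.sum() == f(x)`` exactly.
    """
    background = np.atleast_2d(np.asarray(background, dtype=np.float64))
    instances = np.atleast_2d(np.asarray(instances, dtype=np.float64))
    if background.shape[1] != instances.shape[1]:
        raise ValueError("feature-dimension mismatch between background and instances")
    m, d = instances.shape
    if d > MAX_EXACT_DIM:
        raise ValueError(f"exact enumeration limited to {MAX_EXACT_DIM} features, got {d}")

    n_b = len(background)
    # v[S] per instance: mean over background rows of f with S replaced
    subset_values: dict[frozenset, np.ndarray] = {}
    for r in range(d + 1):
        for S in combinations(range(d), r):
            S = frozenset(S)
            X = np.repeat(background[None, :, :], m, axis=0)  # (m, n_b, d)
            for j in S:
                X[:, :, j] = instances[:, None, j]
            vals = predict_fn(X.reshape(m * n_b, d)).reshape(m, n_b)
            subset_values[S] = vals.mean(axis=1)

    phi = np.zeros((m, d))
    for j in range(d):
        for S, vS in subset_values.items():
            if j in S:
                continue
            w = factorial(len(S)) * factorial(d - len(S) - 1) / factorial(d)
            phi[:, j] += w * (subset_values[S | {j}] - vS)
    base = float(subset_values[frozenset()].mean())
    return phi, base


@dataclass
class ExplainReport:
    """Shapley attributions over PC inputs plus per-PC class attribution."""

    shap_values: pd.DataFrame  # subjects x PCs, signed
    base_value: float
    pc_scores: pd.DataFrame  # subjects x PCs
    class_attribution: pd.DataFrame | None = None  # PCs x feature classes
    mean_abs_shap: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.mean_abs_shap = self.shap_values.abs().mean().rename("mean_abs_shap")

    def ranked_pcs(self) -> list[str]:
        return list(self.mean_abs_shap.sort_values(ascending=False).index)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "base_value": self.base_value,
            "mean_abs_shap": self.mean_abs_shap.to_dict(),
            "shap_values": self.shap_values.to_dict(orient="index"),
            "pc_scores": self.pc_scores.to_dict(orient="index"),
        }
        if self.class_attribution is not None:
            payload["class_attribution"] = self.class_attribution.to_dict(orient="index")
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def shap_explain(
    model, background: pd.DataFrame, instances: pd.DataFrame
) -> ExplainReport:
    """Shapley attributions of the model's decision score over its PC (or
    selected-feature) inputs.  Positive values push toward class 1."""
    if background.empty:
        raise ValueError("background set must be non-empty")
    fn = _decision_function(model)
    phi, base = exact_shapley(
        fn, background.to_numpy(dtype=np.float64), instances.to_numpy(dtype=np.float64)
    )
    shap_df = pd.DataFrame(phi, index=instances.index, columns=instances.columns)
    return ExplainReport(shap_values=shap_df, base_value=base, pc_scores=instances.copy())


def pc_class_attribution(
    loadings: np.ndarray,
    feature_names: list[str],
    class_of: dict[str, str],
) -> pd.DataFrame:
    """Per-PC feature-class attribution via the half-max squared-loading rule.

    Per PC: square each loading, keep values strictly greater than half the
    PC's maximum squared loading (the maximum itself always survives), sum
    kept values per feature class.  Returns PCs x classes plus the dominant
    class per PC.
    """
    loadings = np.atleast_2d(np.asarray(loadings, dtype=np.float64))
    if loadings.shape[1] == 0 or loadings.shape[1] != len(feature_names):
        raise ValueError("loadings columns must map 1:1 to feature names")
    classes = [class_of[n] for n in feature_names]
    rows = []
    for k in range(loadings.shape[0]):
        sq = loadings[k] ** 2
        keep = sq > 0.5 * sq.max()
        if not keep.any():  # all-zero loading row: keep the (flat) maximum
            keep = sq == sq.max()
        sums = {c: 0.0 for c in CLASS_ORDER}
        for c, s, kept in zip(classes, sq, keep):
            if kept:
                sums.setdefault(c, 0.0)
                sums[c] += float(s)
        dominant = max(sums, key=lambda c: sums[c])
        rows.append({"PC": f"PC{k+1}", **sums, "dominant": dominant})
    return pd.DataFrame(rows).set_index("PC")


def explain_final_model(
    fold_model, table_data: pd.DataFrame, class_of: dict[str, str]
) -> ExplainReport:
    """Full explanation of a fitted final model (from ``fit_final``):
    Shapley over the PC scores of the cohort plus, when the selector is a
    PCA variant, the class attribution of its loadings."""
    scores = fold_model.transform(table_data)
    report = shap_explain(fold_model.classifier, scores, scores)
    sel = fold_model.selector
    if sel.projection_loadings is not None:
        report.class_attribution = pc_class_attribution(
            sel.projection_loadings, sel.projection_input_names, class_of
        )
    return report
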