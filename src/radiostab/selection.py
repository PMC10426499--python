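"""Relevance selection: p-value, LASSO, ssLASSO, PCA, ssPCA and SFS.

Every selector is fitted on training subjects only and returns a
:class:`SelectorResult` whose ``apply`` projects any (held-out) subjects
into the selected space.  Inputs are assumed z-scored and redundancy-
filtered upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold, cross_val_score

logger = logging.getLogger(__name__)

SELECTOR_NAMES = ("p-value", "LASSO", "ssLASSO", "PCA", "ssPCA", "SFS")

DEFAULT_ALPHA = 0.05
DEFAULT_VARIANCE_TARGET = 0.95
DEFAULT_SFS_THRESHOLD = 0.02


@dataclass
class SelectorResult:
    method: str
    retained: list[str] | None = None
    projection_mean: np.ndarray | None = field(default=None, repr=False)
    projection_loadings: np.ndarray | None = field(default=None, repr=False)  # (k, d)
    projection_input_names: list[str] | None = None
    n_components: int | None = None
    explained_variance_ratio: np.ndarray | None = field(default=None, repr=False)
    fitted_on: list[str] = field(default_factory=list)

    @property
    def n_selected(self) -> int:
        if self.retained is not None:
            return len(self.retained)
        return int(self.n_components or 0)

    def apply(self, data: pd.DataFrame) -> pd.DataFrame:
        """Project subjects (rows) into the selected feature space."""
        if self.retained is not None:
            return data[self.retained].copy()
        X = data[self.projection_input_names].to_numpy(dtype=np.float64)
        scores = (X - self.projection_mean) @ self.projection_loadings.T
        cols = [f"PC{i+1}" for i in range(scores.shape[1])]
        return pd.DataFrame(scores, index=data.index, columns=cols)


def _check_two_classes(labels: pd.Series) -> None:
    if labels.nunique() < 2:
        raise ValueError("training set must contain both classes")


def select_pvalue(
    data: pd.DataFrame, labels: pd.Series, alpha: float = DEFAULT_ALPHA
) -> SelectorResult:
    """Wilcoxon rank-sum test per feature; keep p < alpha."""
    _check_two_classes(labels)
    g0 = data[labels == 0]
    g1 = data[labels == 1]
    retained = []
    for name in data.columns:
        p = stats.ranksums(g0[name], g1[name]).pvalue
        if p < alpha:
            retained.append(name)
    return SelectorResult("p-value", retained=retained, fitted_on=list(data.index))


def select_lasso(
    data: pd.DataFrame,
    labels: pd.Series,
    C: float | None = None,
    seed: int = 0,
) -> SelectorResult:
    """Features with nonzero coefficients in an L1-penalized logistic model.

    The penalty is chosen by stratified internal CV unless a fixed ``C``
    (inverse of lambda) is given.
    """
    _check_two_classes(labels)
    X = data.to_numpy(dtype=np.float64)
    y = labels.to_numpy()
    if C is not None:
        model = LogisticRegression(
            penalty="l1", C=C, solver="liblinear", random_state=seed, max_iter=5000
        )
    else:
        n_splits = min(5, int(np.bincount(y).min()))
        model = LogisticRegressionCV(
            penalty="l1",
            solver="liblinear",
            Cs=np.logspace(-2, 2, 10),
            cv=StratifiedKFold(n_splits=max(2, n_splits), shuffle=True, random_state=seed),
            random_state=seed,
            max_iter=5000,
        )
    model.fit(X, y)
    coef = model.coef_.ravel()
    retained = [n for n, c in zip(data.columns, coef) if c != 0.0]
    return SelectorResult("LASSO", retained=retained, fitted_on=list(data.index))


def select_sslasso(
    data: pd.DataFrame,
    labels: pd.Series,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
) -> SelectorResult:
    """p-value pre-filter, then LASSO on the survivors."""
    stage1 = select_pvalue(data, labels, alpha)
    if not stage1.retained:
        logger.warning("ssLASSO: p-value stage retained nothing; returning empty set")
        return SelectorResult("ssLASSO", retained=[], fitted_on=list(data.index))
    res = select_lasso(data[stage1.retained], labels, seed=seed)
    return SelectorResult("ssLASSO", retained=res.retained, fitted_on=list(data.index))


def fit_pca(
    data: pd.DataFrame,
    variance_target: float = DEFAULT_VARIANCE_TARGET,
    method_name: str = "PCA",
) -> SelectorResult:
    """PCA of the training features; keep the smallest number of components
    whose cumulative explained variance reaches the target."""
    if len(data) < 2:
        raise ValueError("PCA needs at least 2 training subjects")
    X = data.to_numpy(dtype=np.float64)
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("zero-variance table")
    pca = PCA(svd_solver="full")
    pca.fit(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    k = min(k, len(cum))
    return SelectorResult(
        method_name,
        projection_mean=pca.mean_,
        projection_loadings=pca.components_[:k],
        projection_input_names=list(data.columns),
        n_components=k,
        explained_variance_ratio=pca.explained_variance_ratio_[:k],
        fitted_on=list(data.index),
    )


def apply_pca(result: SelectorResult, data: pd.DataFrame) -> pd.DataFrame:
    return result.apply(data)


def select_sspca(
    data: pd.DataFrame,
    labels: pd.Series,
    alpha: float = DEFAULT_ALPHA,
    variance_target: float = DEFAULT_VARIANCE_TARGET,
) -> SelectorResult:
    """p-value pre-filter, then PCA on the survivors."""
    stage1 = select_pvalue(data, labels, alpha)
    if not stage1.retained:
        logger.warning("ssPCA: p-value stage retained nothing; returning empty set")
        return SelectorResult("ssPCA", retained=[], fitted_on=list(data.index))
    res = fit_pca(data[stage1.retained], variance_target, method_name="ssPCA")
    res.fitted_on = list(data.index)
    return res


def select_sfs(
    data: pd.DataFrame,
    labels: pd.Series,
    model=None,
    improvement_threshold: float = DEFAULT_SFS_THRESHOLD,
    cv: int = 3,
    seed: int = 0,
) -> SelectorResult:
    """Greedy forward selection scored by internal CV accuracy of ``model``.

    Stops when the best single-feature addition improves the score by less
    than ``improvement_threshold``.
    """
    _check_two_classes(labels)
    if model is None:
        from sklearn.svm import SVC

        model = SVC(kernel="rbf")
    y = labels.to_numpy()
    splitter = StratifiedKFold(
        n_splits=min(cv, int(np.bincount(y).min())), shuffle=True, random_state=seed
    )

    def score(features: list[str]) -> float:
        X = data[features].to_numpy(dtype=np.float64)
        return float(np.mean(cross_val_score(clone(model), X, y, cv=splitter, scoring="accuracy")))

    selected: list[str] = []
    current = 0.0
    remaining = list(data.columns)
    while remaining:
        scores = [(score(selected + [f]), f) for f in remaining]
        best_score, best_feat = max(scores, key=lambda t: (t[0], t[1]))
        if best_score - current < improvement_threshold:
            break
        selected.append(best_feat)
        remaining.remove(best_feat)
        current = best_score
    return SelectorResult("SFS", retained=selected, fitted_on=list(data.index))


def fit_selector(
    name: str,
    data: pd.DataFrame,
    labels: pd.Series,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    variance_target: float = DEFAULT_VARIANCE_TARGET,
    sfs_threshold: float = DEFAULT_SFS_THRESHOLD,
    sfs_model=None,
) -> SelectorResult:
    """Dispatch a selector by its name."""
    if name == "p-value":
        return select_pvalue(data, labels, alpha)
    if name == "LASSO":
        return select_lasso(data, labels, seed=seed)
    if name == "ssLASSO":
        return select_sslasso(data, labels, alpha=alpha, seed=seed)
    if name == "PCA":
        return fit_pca(data, variance_target)
    if name == "ssPCA":
        return select_sspca(data, labels, alpha=alpha, variance_target=variance_target)
    if name == "SFS":
        return select_sfs(
            data, labels, model=sfs_model, improvement_threshold=sfs_threshold, seed=seed
        )
    raise ValueError(f"unknown selector {name!r}; choose from {SELECTOR_NAMES}")
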