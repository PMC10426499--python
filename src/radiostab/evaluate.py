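"""Leave-one-out evaluation grid: thresholds x selectors x classifiers.

Per fold, strictly inside the training subjects: z-score fit, Spearman
redundancy filter, relevance selector, SMOTE doubling, classifier fit;
then the single held-out subject is predicted.  Metrics are computed from
the pooled LOO confusion matrix (class 1 = positive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from radiostab.augment import SmoteConfig, smote_augment
from radiostab.features.table import FeatureTable
from radiostab.redundancy import CANDIDATE_THRESHOLDS, correlation_filter
from radiostab.selection import (
    DEFAULT_ALPHA,
    DEFAULT_SFS_THRESHOLD,
    DEFAULT_VARIANCE_TARGET,
    SELECTOR_NAMES,
    SelectorResult,
    fit_selector,
)

logger = logging.getLogger(__name__)

CLASSIFIER_NAMES = ("kNN", "SVM", "DT", "LR", "GB")

DEFAULT_CLASSIFIER_PARAMS: dict[str, dict] = {
    "kNN": {"n_neighbors": 5},
    "SVM": {"kernel": "rbf", "C": 1.0},
    "DT": {"max_depth": None},
    "LR": {"C": 1.0, "max_iter": 2000},
    "GB": {"n_estimators": 100, "learning_rate": 0.1},
}


def make_classifier(name: str, params: dict | None = None, seed: int = 0):
    p = dict(DEFAULT_CLASSIFIER_PARAMS.get(name, {}))
    p.update(params or {})
    if name == "kNN":
        return KNeighborsClassifier(**p)
    if name == "SVM":
        return SVC(random_state=seed, **p)
    if name == "DT":
        return DecisionTreeClassifier(random_state=seed, **p)
    if name == "LR":
        return LogisticRegression(random_state=seed, **p)
    if name == "GB":
        return GradientBoostingClassifier(random_state=seed, **p)
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIER_NAMES}")


def metrics(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    """Accuracy, sensitivity and specificity (class 1 positive).

    Ratios with a zero denominator are reported as NaN (missing), never 0.
    """
    counts = (tp, tn, fp, fn)
    if any(c < 0 for c in counts):
        raise ValueError("negative confusion counts")
    total = sum(counts)
    if total == 0:
        raise ValueError("empty confusion matrix")
    sens = tp / (tp + fn) if (tp + fn) > 0 else np.nan
    spec = tn / (tn + fp) if (tn + fp) > 0 else np.nan
    return {
        "accuracy": (tp + tn) / total,
        "sensitivity": sens,
        "specificity": spec,
    }


@dataclass
class RunConfig:
    thresholds: tuple[float, ...] = CANDIDATE_THRESHOLDS
    selectors: tuple[str, ...] = SELECTOR_NAMES
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES
    classifier_params: dict[str, dict] = field(default_factory=dict)
    alpha: float = DEFAULT_ALPHA
    variance_target: float = DEFAULT_VARIANCE_TARGET
    sfs_threshold: float = DEFAULT_SFS_THRESHOLD
    smote_q: int = 5
    use_smote: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.thresholds and self.selectors and self.classifiers):
            raise ValueError("thresholds, selectors and classifiers must be non-empty")


@dataclass
class FoldModel:
    """Everything fitted inside one training fold for one grid cell."""

    zscore_mean: pd.Series
    zscore_std: pd.Series
    retained: list[str]
    selector: SelectorResult
    classifier: object = field(repr=False)

    def transform(self, data: pd.DataFrame) -> pd.DataFrame:
        z = (data - self.zscore_mean) / self.zscore_std
        return self.selector.apply(z[self.retained])

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        return self.classifier.predict(self.transform(data).to_numpy(dtype=np.float64))


def _zscore_params(data: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    mean = data.mean()
    std = data.std(ddof=0)
    std = std.where(std > 0, 1.0)  # constant features pass through centred
    return mean, std


def fit_fold(
    table: FeatureTable,
    train_ids: list[str],
    threshold: float,
    selector_name: str,
    classifier_name: str,
    cfg: RunConfig | None = None,
    fold_seed: int | None = None,
) -> FoldModel:
    """Fit the full per-fold pipeline on ``train_ids`` only."""
    cfg = cfg or RunConfig()
    seed = cfg.seed if fold_seed is None else fold_seed
    train = table.subset_subjects(train_ids)
    mean, std = _zscore_params(train.data)
    z = (train.data - mean) / std

    retained = correlation_filter(z, threshold)
    z = z[retained]

    selector = fit_selector(
        selector_name,
        z,
        train.labels,
        seed=seed,
        alpha=cfg.alpha,
        variance_target=cfg.variance_target,
        sfs_threshold=cfg.sfs_threshold,
        sfs_model=make_classifier(classifier_name, cfg.classifier_params.get(classifier_name), seed),
    )
    if selector.n_selected == 0:
        raise ValueError(f"selector {selector_name} returned zero features")

    Xsel = selector.apply(z)
    y = train.labels
    if cfg.use_smote:
        Xsel, y = smote_augment(Xsel, y, SmoteConfig(q_neighbors=cfg.smote_q, seed=seed))

    clf = make_classifier(classifier_name, cfg.classifier_params.get(classifier_name), seed)
    clf.fit(Xsel.to_numpy(dtype=np.float64), y.to_numpy())
    return FoldModel(mean, std, retained, selector, clf)


@dataclass
class GridResult:
    cells: pd.DataFrame  # (threshold, selector, classifier) x metrics
    predictions: pd.DataFrame  # per-fold predictions
    counts: pd.DataFrame  # mean +/- SD of selected-feature counts per cell
    failed: list[tuple] = field(default_factory=list)

    def summary_by_classifier(self) -> pd.DataFrame:
        """Median accuracy per classifier across thresholds (per selector)."""
        return (
            self.cells.groupby(["selector", "classifier"])["accuracy"]
            .median()
            .unstack("classifier")
        )


def loo_run(table: FeatureTable, cfg: RunConfig | None = None) -> GridResult:
    """Sweep the grid with leave-one-out cross-validation."""
    cfg = cfg or RunConfig()
    ids = list(table.data.index)
    n = len(ids)
    if n < 4:
        raise ValueError("need at least 4 subjects for a LOO run")
    if table.labels.nunique() < 2:
        raise ValueError("both classes must be present")

    pred_rows = []
    count_rows = []
    failed = []
    for t_idx, threshold in enumerate(cfg.thresholds):
        for s_idx, selector_name in enumerate(cfg.selectors):
            for c_idx, classifier_name in enumerate(cfg.classifiers):
                for fold, held_out in enumerate(ids):
                    train_ids = [i for i in ids if i != held_out]
                    fold_seed = cfg.seed * 100003 + fold
                    try:
                        fm = fit_fold(
                            table, train_ids, threshold, selector_name,
                            classifier_name, cfg, fold_seed=fold_seed,
                        )
                    except ValueError as exc:
                        logger.warning(
                            "cell (%s, %s, %s) fold %d failed: %s",
                            threshold, selector_name, classifier_name, fold, exc,
                        )
                        failed.append((threshold, selector_name, classifier_name, fold))
                        continue
                    pred = int(fm.predict(table.data.loc[[held_out]])[0])
                    pred_rows.append(
                        {
                            "threshold": threshold,
                            "selector": selector_name,
                            "classifier": classifier_name,
                            "fold": fold,
                            "subject_id": held_out,
                            "true": int(table.labels.loc[held_out]),
                            "predicted": pred,
                            "n_selected": fm.selector.n_selected,
                        }
                    )
                    if c_idx == 0:
                        count_rows.append(
                            {
                                "threshold": threshold,
                                "selector": selector_name,
                                "fold": fold,
                                "n_selected": fm.selector.n_selected,
                                "n_retained_corr": len(fm.retained),
                            }
                        )

    predictions = pd.DataFrame(pred_rows)
    cell_rows = []
    if not predictions.empty:
        for (thr, sel, clf), grp in predictions.groupby(
            ["threshold", "selector", "classifier"]
        ):
            tp = int(((grp["true"] == 1) & (grp["predicted"] == 1)).sum())
            tn = int(((grp["true"] == 0) & (grp["predicted"] == 0)).sum())
            fp = int(((grp["true"] == 0) & (grp["predicted"] == 1)).sum())
            fn = int(((grp["true"] == 1) & (grp["predicted"] == 0)).sum())
            m = metrics(tp, tn, fp, fn)
            cell_rows.append(
                {"threshold": thr, "selector": sel, "classifier": clf,
                 "tp": tp, "tn": tn, "fp": fp, "fn": fn, **m}
            )
    cells = pd.DataFrame(cell_rows)

    counts_df = pd.DataFrame(count_rows)
    if not counts_df.empty:
        counts = (
            counts_df.groupby(["threshold", "selector"])["n_selected"]
            .agg(["mean", "std"])
            .reset_index()
        )
    else:
        counts = pd.DataFrame(columns=["threshold", "selector", "mean", "std"])
    return GridResult(cells=cells, predictions=predictions, counts=counts, failed=failed)


def fit_final(
    table: FeatureTable,
    threshold: float,
    selector_name: str,
    classifier_name: str,
    cfg: RunConfig | None = None,
) -> FoldModel:
    """Final model: same fold-fitting code path with the full cohort as the
    training set (SMOTE included)."""
    return fit_fold(
        table, list(table.data.index), threshold, selector_name, classifier_name, cfg
    )
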