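"""Subjects x features tables with labels and feature-class annotations."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from radiostab.features.extractor import (
    ExtractionConfig,
    FeatureVector,
    extract_features,
    feature_class_map,
)

LABEL_COLUMN = "label"


@dataclass
class FeatureTable:
    """Rows = subjects, columns = named features, plus binary labels."""

    data: pd.DataFrame
    labels: pd.Series
    class_of: dict[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        self.labels = self.labels.reindex(self.data.index)
        if self.labels.isna().any():
            raise ValueError("every subject needs a label")
        self.labels = self.labels.astype(int)
        missing = [c for c in self.data.columns if c not in self.class_of]
        if missing:
            raise ValueError(f"features without a class annotation: {missing[:3]}...")

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def subset_features(self, names: list[str]) -> "FeatureTable":
        return FeatureTable(self.data[names].copy(), self.labels.copy(), dict(self.class_of))

    def subset_subjects(self, ids) -> "FeatureTable":
        return FeatureTable(
            self.data.loc[list(ids)].copy(), self.labels.loc[list(ids)].copy(), dict(self.class_of)
        )

    def to_csv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        """CSV with the label as first column; feature->class map as JSON."""
        path = Path(path)
        out = self.data.copy()
        out.insert(0, LABEL_COLUMN, self.labels)
        out.to_csv(path, index_label="subject_id")
        sidecar = Path(sidecar) if sidecar else path.with_suffix(".classes.json")
        sidecar.write_text(json.dumps(self.class_of, indent=1, sort_keys=True))

    @classmethod
    def from_csv(cls, path: str | Path, sidecar: str | Path | None = None) -> "FeatureTable":
        path = Path(path)
        df = pd.read_csv(path, index_col="subject_id")
        labels = df.pop(LABEL_COLUMN)
        sidecar = Path(sidecar) if sidecar else path.with_suffix(".classes.json")
        if sidecar.exists():
            class_of = json.loads(sidecar.read_text())
        else:
            class_of = feature_class_map(list(df.columns))
        return cls(df, labels, class_of)


def build_feature_table(
    cohort,
    cfg: ExtractionConfig | None = None,
    subject_ids: list[str] | None = None,
) -> FeatureTable:
    """Extract features for every (volume, label) pair of a cohort.

    All subjects must yield identical feature names; an empty cohort is an
    error.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("empty cohort")
    if subject_ids is None:
        subject_ids = [f"s{i:03d}" for i in range(len(cohort))]
    if len(subject_ids) != len(cohort):
        raise ValueError("subject_ids length mismatch")

    rows: list[FeatureVector] = [extract_features(v, cfg) for v, _ in cohort]
    names = list(rows[0].values)
    for sid, fv in zip(subject_ids, rows):
        if list(fv.values) != names:
            raise ValueError(f"inconsistent feature names for subject {sid}")

    data = pd.DataFrame(
        np.array([[fv.values[n] for n in names] for fv in rows], dtype=np.float64),
        index=pd.Index(subject_ids, name="subject_id"),
        columns=names,
    )
    labels = pd.Series([lab for _, lab in cohort], index=data.index, name=LABEL_COLUMN)
    return FeatureTable(data, labels, rows[0].class_of)
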