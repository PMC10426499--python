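"""Translation-based feature robustness screening.

Non-shape features are extracted on the original ROI and on 8 translated
copies (+/- minimal and +/- maximal entity, along x and y).  For each
translation direction an absolute-agreement ICC across subjects compares
original vs translated values; a feature is *stable* if the mean ICC over
the 4 minimal translations exceeds 0.75 and *discriminative* if the mean
ICC over the 4 maximal translations is below 0.5.  Robust = both.
Shape-size features bypass the screen (a rigid translation cannot change
them) and are always retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from radiostab.core import AXIS_NAMES, DegenerateFeatureError, VolumeWithMask
from radiostab.features.extractor import (
    CLASS_FIRST_ORDER,
    CLASS_SHAPE,
    CLASS_TEXTURAL,
    ExtractionConfig,
    extract_features,
    feature_names,
)

logger = logging.getLogger(__name__)

MINIMAL_FRACTION = 0.005
MAXIMAL_FRACTION = 0.30
STABILITY_THRESHOLD = 0.75
DISCRIMINATION_THRESHOLD = 0.5

ALLOWED_FRACTIONS = (0.0, MINIMAL_FRACTION, MAXIMAL_FRACTION)


@dataclass(frozen=True)
class TranslationSpec:
    """Signed translation as a fraction of the ROI bounding-box length."""

    fraction: float
    axis: str  # "x" (medial-lateral) or "y" (antero-posterior)

    def __post_init__(self) -> None:
        if self.axis not in ("x", "y"):
            raise ValueError("axis must be 'x' or 'y'")
        if not any(np.isclose(abs(self.fraction), f) for f in ALLOWED_FRACTIONS):
            raise ValueError(
                f"|fraction| must be one of {ALLOWED_FRACTIONS}, got {self.fraction}"
            )

    @property
    def axis_index(self) -> int:
        return AXIS_NAMES.index(self.axis)


def screening_specs() -> list[TranslationSpec]:
    """The 8 canonical translations: +/- minimal and +/- maximal, x and y."""
    return [
        TranslationSpec(sign * frac, ax)
        for frac in (MINIMAL_FRACTION, MAXIMAL_FRACTION)
        for ax in ("x", "y")
        for sign in (+1, -1)
    ]


def translate_mask(
    v: VolumeWithMask, spec: TranslationSpec, subject: str = "?"
) -> VolumeWithMask:
    """Rigidly shift the mask by ``fraction x bounding-box length`` along the
    axis, rounded to whole voxels with a floor of 1 voxel (so the minimal
    entity is never a no-op).  Intensities are untouched."""
    if spec.fraction == 0:
        return VolumeWithMask(v.intensities, v.spacing, v.mask.copy())
    ax = spec.axis_index
    lo, hi = v.mask_bounding_box()[ax]
    box_len = hi - lo + 1
    shift = max(1, int(round(abs(spec.fraction) * box_len)))
    shift *= 1 if spec.fraction > 0 else -1

    n = v.shape[ax]
    if lo + shift < 0 or hi + shift >= n:
        raise ValueError(
            f"translation clips the mask at the boundary (subject {subject}, "
            f"fraction {spec.fraction:+} along {spec.axis}, shift {shift} voxels)"
        )
    new_mask = np.zeros_like(v.mask)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    if shift > 0:
        src[ax], dst[ax] = slice(0, n - shift), slice(shift, n)
    else:
        src[ax], dst[ax] = slice(-shift, n), slice(0, n + shift)
    new_mask[tuple(dst)] = v.mask[tuple(src)]
    assert new_mask.sum() == v.mask.sum()
    return VolumeWithMask(v.intensities, v.spacing, new_mask)


def overlap_fraction(original_mask: np.ndarray, translated_mask: np.ndarray) -> float:
    """Percentage of the original ROI volume inside the translated ROI."""
    original_mask = np.asarray(original_mask, dtype=bool)
    translated_mask = np.asarray(translated_mask, dtype=bool)
    if original_mask.shape != translated_mask.shape:
        raise ValueError("masks must share a grid")
    n = original_mask.sum()
    if n == 0:
        raise ValueError("empty original mask")
    return 100.0 * float((original_mask & translated_mask).sum()) / float(n)


def icc(a, b) -> float:
    """Two-way, absolute-agreement, single-measure ICC (Shrout-Fleiss
    ICC(2,1) / ICC(A,1)) between paired measurements across subjects.

    Raises :class:`DegenerateFeatureError` when all values are equal in both
    vectors but the vectors differ is impossible; identical constant vectors
    return 1.0, differing constant vectors raise.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1D vectors")
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values")

    if np.array_equal(a, b):
        return 1.0  # perfect agreement, constant or not
    Y = np.stack([a, b], axis=1)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise DegenerateFeatureError("both vectors constant but unequal")

    k = 2
    grand = Y.mean()
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((Y - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / 1.0
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise DegenerateFeatureError("zero denominator in ICC")
    return float(np.clip((msr - mse) / denom, -1.0, 1.0))


@dataclass
class RobustnessReport:
    """Per-feature ICCs for the 4 minimal and 4 maximal translations."""

    table: pd.DataFrame  # index: feature; columns: icc_min_1..4, means, flags
    overlap: pd.DataFrame  # per (subject, spec): overlap percentage
    shape_features: list[str] = field(default_factory=list)
    degenerate: list[str] = field(default_factory=list)

    @property
    def robust_features(self) -> list[str]:
        return list(self.table.index[self.table["robust"]])

    @property
    def retained_features(self) -> list[str]:
        """All shape-size features + robust non-shape features."""
        return self.shape_features + self.robust_features

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(Path(path), index_label="feature")

    @classmethod
    def from_csv(cls, path: str | Path) -> "RobustnessReport":
        df = pd.read_csv(Path(path), index_col="feature")
        for c in ("stable", "discriminative", "robust"):
            df[c] = df[c].astype(bool)
        return cls(df, pd.DataFrame(), feature_names((CLASS_SHAPE,)), [])


def robustness_screen(
    cohort,
    extraction_cfg: ExtractionConfig | None = None,
) -> RobustnessReport:
    """Run the full translation screen on a (preprocessed) cohort.

    ``cohort`` is a sequence of ``(VolumeWithMask, label)`` pairs.  Needs at
    least 3 subjects for the ICC to be defined.
    """
    volumes = [v for v, _ in cohort]
    if len(volumes) < 3:
        raise ValueError("robustness screen needs >= 3 subjects")
    extraction_cfg = extraction_cfg or ExtractionConfig()
    nonshape_cfg = ExtractionConfig(
        bin_width=extraction_cfg.bin_width,
        enabled_classes=(CLASS_FIRST_ORDER, CLASS_TEXTURAL),
        gldm_alpha=extraction_cfg.gldm_alpha,
    )
    specs = screening_specs()

    names = None
    original: list[dict[str, float]] = []
    translated: dict[TranslationSpec, list[dict[str, float]]] = {s: [] for s in specs}
    overlap_rows = []
    for i, v in enumerate(volumes):
        fv = extract_features(v, nonshape_cfg)
        if names is None:
            names = list(fv.values)
        original.append(fv.values)
        for spec in specs:
            tv = translate_mask(v, spec, subject=f"s{i:03d}")
            translated[spec].append(extract_features(tv, nonshape_cfg).values)
            overlap_rows.append(
                {
                    "subject": f"s{i:03d}",
                    "fraction": spec.fraction,
                    "axis": spec.axis,
                    "overlap_pct": overlap_fraction(v.mask, tv.mask),
                }
            )

    min_specs = [s for s in specs if np.isclose(abs(s.fraction), MINIMAL_FRACTION)]
    max_specs = [s for s in specs if np.isclose(abs(s.fraction), MAXIMAL_FRACTION)]

    rows = {}
    degenerate = []
    for feat in names:
        orig = np.array([d[feat] for d in original])
        row: dict[str, float | bool] = {}
        bad = False
        for tag, group in (("icc_min", min_specs), ("icc_max", max_specs)):
            vals = []
            for j, spec in enumerate(group, start=1):
                trans = np.array([d[feat] for d in translated[spec]])
                try:
                    val = icc(orig, trans)
                except DegenerateFeatureError:
                    bad = True
                    val = np.nan
                row[f"{tag}_{j}"] = val
                vals.append(val)
            row[f"{tag}_mean"] = float(np.nanmean(vals)) if not bad else np.nan
        if bad or (np.ptp(orig) == 0 and row.get("icc_min_mean") == 1.0):
            # constant across subjects and translations: no information
            degenerate.append(feat)
            logger.warning("feature %s is degenerate (zero variance); excluded", feat)
            row["stable"] = row["discriminative"] = row["robust"] = False
        else:
            row["stable"] = bool(row["icc_min_mean"] > STABILITY_THRESHOLD)
            row["discriminative"] = bool(row["icc_max_mean"] < DISCRIMINATION_THRESHOLD)
            row["robust"] = bool(row["stable"] and row["discriminative"])
        rows[feat] = row

    cols = (
        [f"icc_min_{j}" for j in range(1, 5)]
        + ["icc_min_mean"]
        + [f"icc_max_{j}" for j in range(1, 5)]
        + ["icc_max_mean"]
        + ["stable", "discriminative", "robust"]
    )
    table = pd.DataFrame.from_dict(rows, orient="index")[cols]
    table.index.name = "feature"
    return RobustnessReport(
        table=table,
        overlap=pd.DataFrame(overlap_rows),
        shape_features=feature_names((CLASS_SHAPE,)),
        degenerate=degenerate,
    )
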