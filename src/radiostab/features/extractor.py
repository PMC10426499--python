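"""Radiomic feature extraction: 107 named features per ROI.

Feature names are namespaced ``<class>/<family>/<name>`` where class is one
of ``shape-size`` (14), ``first-order`` (18) or ``textural`` (75: GLCM 24,
GLRLM 16, GLSZM 16, GLDM 14, NGTDM 5).  The pinned extraction parameters
live in ``extraction_params.yaml`` next to this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from radiostab.core import VolumeWithMask
from radiostab.features import texture
from radiostab.features.discretize import discretize_volume
from radiostab.features.firstorder import FIRST_ORDER_NAMES, first_order_features
from radiostab.features.shape import SHAPE_NAMES, shape_features

CLASS_SHAPE = "shape-size"
CLASS_FIRST_ORDER = "first-order"
CLASS_TEXTURAL = "textural"

EXPECTED_COUNTS = {CLASS_SHAPE: 14, CLASS_FIRST_ORDER: 18, CLASS_TEXTURAL: 75}

_TEXTURE_FAMILIES = (
    ("glcm", texture.GLCM_NAMES),
    ("glrlm", texture.GLRLM_NAMES),
    ("glszm", texture.GLSZM_NAMES),
    ("gldm", texture.GLDM_NAMES),
    ("ngtdm", texture.NGTDM_NAMES),
)


def feature_names(enabled_classes: tuple[str, ...] | None = None) -> list[str]:
    """All 107 namespaced feature names (optionally restricted by class)."""
    names = []
    if enabled_classes is None or CLASS_SHAPE in enabled_classes:
        names += [f"{CLASS_SHAPE}/shape/{n}" for n in SHAPE_NAMES]
    if enabled_classes is None or CLASS_FIRST_ORDER in enabled_classes:
        names += [f"{CLASS_FIRST_ORDER}/firstorder/{n}" for n in FIRST_ORDER_NAMES]
    if enabled_classes is None or CLASS_TEXTURAL in enabled_classes:
        for family, fam_names in _TEXTURE_FAMILIES:
            names += [f"{CLASS_TEXTURAL}/{family}/{n}" for n in fam_names]
    return names


def feature_class_map(names: list[str] | None = None) -> dict[str, str]:
    """feature name -> feature class."""
    return {n: n.split("/", 1)[0] for n in (names or feature_names())}


def non_shape_feature_names() -> list[str]:
    return feature_names((CLASS_FIRST_ORDER, CLASS_TEXTURAL))


@dataclass
class ExtractionConfig:
    bin_width: float = 0.5
    enabled_classes: tuple[str, ...] = (CLASS_SHAPE, CLASS_FIRST_ORDER, CLASS_TEXTURAL)
    gldm_alpha: int = 0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        unknown = set(self.enabled_classes) - set(EXPECTED_COUNTS)
        if unknown:
            raise ValueError(f"unknown feature classes: {sorted(unknown)}")

    @classmethod
    def pinned(cls) -> "ExtractionConfig":
        """The configuration pinned in ``extraction_params.yaml``."""
        text = resources.files("radiostab.features").joinpath(
            "extraction_params.yaml"
        ).read_text()
        params = yaml.safe_load(text)
        return cls(
            bin_width=float(params["discretization"]["bin_width"]),
            gldm_alpha=int(params["gldm"]["alpha"]),
        )


@dataclass
class FeatureVector:
    values: dict[str, float]
    class_of: dict[str, str] = field(repr=False)

    def validate_full(self) -> None:
        """Assert the complete 107-feature contract (14/18/75)."""
        if len(self.values) != 107:
            raise ValueError(f"expected 107 features, got {len(self.values)}")
        counts: dict[str, int] = {}
        for name in self.values:
            counts[self.class_of[name]] = counts.get(self.class_of[name], 0) + 1
        if counts != EXPECTED_COUNTS:
            raise ValueError(f"bad class partition: {counts}")
        bad = [k for k, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite feature values: {bad}")


def _crop_to_mask(v: VolumeWithMask, pad: int = 1) -> tuple[np.ndarray, np.ndarray]:
    bbox = v.mask_bounding_box()
    sl = tuple(
        slice(max(0, lo - pad), min(n, hi + 1 + pad))
        for (lo, hi), n in zip(bbox, v.shape)
    )
    return v.intensities[sl], v.mask[sl]


def extract_features(v: VolumeWithMask, cfg: ExtractionConfig | None = None) -> FeatureVector:
    """Extract the enabled feature classes from one subject.

    Deterministic; raises if the ROI has fewer than 2 voxels (texture is
    undefined on a single voxel).
    """
    cfg = cfg or ExtractionConfig()
    if int(v.mask.sum()) < 2:
        raise ValueError("mask must contain at least 2 voxels")

    img, mask = _crop_to_mask(v)
    values: dict[str, float] = {}

    if CLASS_SHAPE in cfg.enabled_classes:
        fe = shape_features(mask, v.spacing)
        values.update({f"{CLASS_SHAPE}/shape/{k}": fe[k] for k in SHAPE_NAMES})

    need_disc = (CLASS_FIRST_ORDER in cfg.enabled_classes) or (
        CLASS_TEXTURAL in cfg.enabled_classes
    )
    if need_disc:
        disc, ng = discretize_volume(img, mask, cfg.bin_width)

    if CLASS_FIRST_ORDER in cfg.enabled_classes:
        fe = first_order_features(img[mask], disc[mask], v.voxel_volume)
        values.update({f"{CLASS_FIRST_ORDER}/firstorder/{k}": fe[k] for k in FIRST_ORDER_NAMES})

    if CLASS_TEXTURAL in cfg.enabled_classes:
        fams = {
            "glcm": texture.glcm_features(disc, ng),
            "glrlm": texture.glrlm_features(disc, ng),
            "glszm": texture.glszm_features(disc, ng),
            "gldm": texture.gldm_features(disc, ng, alpha=cfg.gldm_alpha),
            "ngtdm": texture.ngtdm_features(disc, ng),
        }
        for family, fam_names in _TEXTURE_FAMILIES:
            values.update(
                {f"{CLASS_TEXTURAL}/{family}/{k}": fams[family][k] for k in fam_names}
            )

    fv = FeatureVector(values=values, class_of=feature_class_map(list(values)))
    if set(cfg.enabled_classes) == set(EXPECTED_COUNTS):
        fv.validate_full()
    return fv
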