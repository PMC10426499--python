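import numpy as np
import pandas as pd
import pytest

from radiostab.core import VolumeWithMask
from radiostab.features.table import FeatureTable
from radiostab.features.extractor import feature_class_map
from radiostab.phantom import PhantomConfig, generate_cohort
from radiostab.preprocess import preprocess


def small_phantom_config(seed: int = 0, n_per_class: int = 2, **overrides) -> PhantomConfig:
    """A fast, coarse phantom: generated directly on a ~2 mm grid."""
    defaults = dict(
        n_subjects_per_class=n_per_class,
        grid_shape=(48, 48, 48),
        voxel_spacing=(2.0, 2.0, 2.0),
        outer_semi_axes_mm=(28.0, 26.0, 24.0),
        inner_semi_axes_mm=(16.0, 15.0, 14.0),
        seed=seed,
    )
    defaults.update(overrides)
    return PhantomConfig(**defaults)


@pytest.fixture(scope="session")
def phantom_subject() -> VolumeWithMask:
    """One preprocessed phantom subject (native 1 mm grid -> 2 mm)."""
    cfg = PhantomConfig(n_subjects_per_class=2, seed=11)
    v, _ = generate_cohort(cfg)[0]
    return preprocess(v)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six coarse subjects (3 per class), no resampling needed."""
    return generate_cohort(small_phantom_config(seed=7, n_per_class=3))


def box_volume(box=(8, 10, 6), shape=(32, 32, 32), value=100.0, spacing=(1.0, 1.0, 1.0)):
    """Solid box ROI centred in a constant volume."""
    img = np.full(shape, value, dtype=float)
    mask = np.zeros(shape, dtype=bool)
    sl = tuple(slice(n // 2 - b // 2, n // 2 - b // 2 + b) for n, b in zip(shape, box))
    mask[sl] = True
    return VolumeWithMask(img, spacing, mask)


def random_feature_table(
    n_subjects=20, n_features=10, seed=0, informative=0, gap=3.0, prefix="f"
) -> FeatureTable:
    """Synthetic feature table; the first ``informative`` features get a
    class-dependent mean shift of ``gap``."""
    rng = np.random.default_rng(seed)
    labels = np.array([0] * (n_subjects // 2) + [1] * (n_subjects - n_subjects // 2))
    X = rng.standard_normal((n_subjects, n_features))
    X[:, :informative] += gap * labels[:, None]
    names = [f"{prefix}{i:03d}" for i in range(n_features)]
    ids = [f"s{i:03d}" for i in range(n_subjects)]
    data = pd.DataFrame(X, index=pd.Index(ids, name="subject_id"), columns=names)
    class_of = {n: "textural" for n in names}
    return FeatureTable(data, pd.Series(labels, index=data.index), class_of)
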