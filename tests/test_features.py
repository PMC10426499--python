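import numpy as np
import pandas as pd
import pytest
from scipy import stats

from radiostab.core import VolumeWithMask
from radiostab.features import (
    CLASS_FIRST_ORDER,
    CLASS_SHAPE,
    CLASS_TEXTURAL,
    ExtractionConfig,
    FeatureTable,
    build_feature_table,
    extract_features,
    feature_names,
)
from radiostab.features.discretize import discretize_fixed_bin_width
from radiostab.features.texture import glcm_features_from_matrix, unique_direction_offsets
from tests.conftest import box_volume, small_phantom_config
from radiostab.phantom import generate_cohort


def _noise_volume(seed=0, box=(8, 9, 7), mean=200.0, sd=20.0):
    rng = np.random.default_rng(seed)
    v = box_volume(box=box)
    img = rng.normal(mean, sd, v.shape)
    return VolumeWithMask(img, v.spacing, v.mask)


# -- contract ---------------------------------------------------------------


def test_107_features_with_class_partition(phantom_subject):
    fv = extract_features(phantom_subject, ExtractionConfig.pinned())
    assert len(fv.values) == 107
    counts = pd.Series(list(fv.class_of.values())).value_counts()
    assert counts[CLASS_SHAPE] == 14
    assert counts[CLASS_FIRST_ORDER] == 18
    assert counts[CLASS_TEXTURAL] == 75
    assert all(np.isfinite(v) for v in fv.values.values())


def test_feature_names_stable_and_namespaced():
    names = feature_names()
    assert len(names) == 107
    assert len(set(names)) == 107
    assert all(n.count("/") == 2 for n in names)


def test_pinned_config_bin_width():
    assert ExtractionConfig.pinned().bin_width == 0.5


def test_extraction_deterministic():
    v = _noise_volume(seed=4)
    a = extract_features(v).values
    b = extract_features(v).values
    assert a == b


def test_mask_below_two_voxels_errors():
    v = box_volume()
    mask = np.zeros(v.shape, dtype=bool)
    mask[5, 5, 5] = True
    with pytest.raises(ValueError, match="2 voxels"):
        extract_features(VolumeWithMask(v.intensities, v.spacing, mask))


# -- first-order oracles ----------------------------------------------------


def test_constant_roi_zero_variance_and_range():
    fv = extract_features(box_volume(value=150.0)).values
    assert fv["first-order/firstorder/Variance"] == 0.0
    assert fv["first-order/firstorder/Range"] == 0.0


def test_three_voxel_mean():
    img = np.zeros((5, 5, 5))
    mask = np.zeros_like(img, dtype=bool)
    for i, hu in enumerate((100.0, 200.0, 300.0)):
        img[1 + i, 2, 2] = hu
        mask[1 + i, 2, 2] = True
    fv = extract_features(VolumeWithMask(img, (1, 1, 1), mask)).values
    assert fv["first-order/firstorder/Mean"] == pytest.approx(200.0)


def test_first_order_against_numpy_oracles():
    v = _noise_volume(seed=8)
    x = v.intensities[v.mask]
    fv = extract_features(v).values
    pre = "first-order/firstorder/"
    assert fv[pre + "Mean"] == pytest.approx(x.mean())
    assert fv[pre + "Variance"] == pytest.approx(x.var())
    assert fv[pre + "Median"] == pytest.approx(np.median(x))
    assert fv[pre + "Minimum"] == pytest.approx(x.min())
    assert fv[pre + "Maximum"] == pytest.approx(x.max())
    assert fv[pre + "Energy"] == pytest.approx(np.sum(x**2))
    assert fv[pre + "RootMeanSquared"] == pytest.approx(np.sqrt(np.mean(x**2)))
    assert fv[pre + "Skewness"] == pytest.approx(stats.skew(x))
    assert fv[pre + "Kurtosis"] == pytest.approx(stats.kurtosis(x, fisher=False))
    assert fv[pre + "MeanAbsoluteDeviation"] == pytest.approx(np.mean(np.abs(x - x.mean())))
    assert fv[pre + "InterquartileRange"] == pytest.approx(
        np.percentile(x, 75) - np.percentile(x, 25)
    )


# -- discretization ---------------------------------------------------------


def test_discretize_levels_start_at_one():
    levels = discretize_fixed_bin_width(np.array([10.0, 10.4, 10.6, 12.0]), 0.5)
    assert levels.min() == 1
    np.testing.assert_array_equal(levels, [1, 1, 2, 5])


def test_discretize_rejects_bad_width():
    with pytest.raises(ValueError):
        discretize_fixed_bin_width(np.array([1.0]), 0.0)


# -- GLCM oracle ------------------------------------------------------------


def brute_force_glcm(disc, off, ng):
    """Independent pair enumeration over voxels (symmetric counts)."""
    P = np.zeros((ng, ng))
    it = np.ndindex(disc.shape)
    for idx in it:
        if disc[idx] == 0:
            continue
        nb = tuple(i + o for i, o in zip(idx, off))
        if any(j < 0 or j >= n for j, n in zip(nb, disc.shape)):
            continue
        if disc[nb] == 0:
            continue
        P[disc[idx] - 1, disc[nb] - 1] += 1
        P[disc[nb] - 1, disc[idx] - 1] += 1
    return P


def test_glcm_contrast_matches_brute_force_pair_enumeration():
    rng = np.random.default_rng(3)
    disc = rng.integers(1, 5, size=(6, 6, 6))
    disc[rng.random(disc.shape) < 0.3] = 0  # holes outside the "ROI"
    ng = 4
    for off in [(1, 0, 0), (0, 1, 1), (1, -1, 1)]:
        P = brute_force_glcm(disc, off, ng)
        present = P.sum(axis=1) > 0
        Pc = P[np.ix_(present, present)]
        lv = np.flatnonzero(present) + 1
        fe = glcm_features_from_matrix(Pc, lv)
        p = P / P.sum()
        expected = sum(
            (i + 1 - (j + 1)) ** 2 * p[i, j] for i in range(ng) for j in range(ng)
        )
        assert fe["Contrast"] == pytest.approx(expected, abs=1e-12)
        # joint entropy oracle
        nz = p[p > 0]
        assert fe["JointEntropy"] == pytest.approx(-np.sum(nz * np.log2(nz)), abs=1e-12)


def test_13_unique_directions():
    offs = unique_direction_offsets()
    assert len(offs) == 13
    assert len({o for o in offs} | {tuple(-x for x in o) for o in offs}) == 26


# -- shape ------------------------------------------------------------------


def test_shape_invariant_to_intensity_rescale(phantom_subject):
    v = phantom_subject
    scaled = VolumeWithMask(v.intensities * 3.7 + 10, v.spacing, v.mask)
    a = extract_features(v, ExtractionConfig(enabled_classes=(CLASS_SHAPE,)))
    b = extract_features(scaled, ExtractionConfig(enabled_classes=(CLASS_SHAPE,)))
    assert a.values == b.values


def test_sphere_shape_oracles():
    # 16 mm radius sphere, 1 mm spacing: volume ~ 4/3 pi r^3, sphericity ~ 1
    shape = (48, 48, 48)
    grid = np.indices(shape) - 23.5
    mask = (grid**2).sum(axis=0) <= 16.0**2
    v = VolumeWithMask(np.full(shape, 100.0), (1.0, 1.0, 1.0), mask)
    fe = extract_features(v, ExtractionConfig(enabled_classes=(CLASS_SHAPE,))).values
    expected_vol = 4.0 / 3.0 * np.pi * 16.0**3
    assert fe["shape-size/shape/MeshVolume"] == pytest.approx(expected_vol, rel=0.03)
    # marching-cubes meshes of voxelized spheres slightly overestimate area
    assert 0.88 < fe["shape-size/shape/Sphericity"] <= 1.0
    assert fe["shape-size/shape/Maximum3DDiameter"] == pytest.approx(32.0, rel=0.06)
    assert fe["shape-size/shape/Elongation"] == pytest.approx(1.0, abs=0.02)
    assert fe["shape-size/shape/Flatness"] == pytest.approx(1.0, abs=0.02)


# -- table ------------------------------------------------------------------


def test_table_shape_and_roundtrip(tmp_path, tiny_cohort):
    table = build_feature_table(tiny_cohort, ExtractionConfig(bin_width=5.0))
    assert table.data.shape == (6, 107)
    path = tmp_path / "table.csv"
    table.to_csv(path)
    back = FeatureTable.from_csv(path)
    pd.testing.assert_frame_equal(table.data, back.data)
    pd.testing.assert_series_equal(table.labels, back.labels, check_names=False)
    assert table.class_of == back.class_of


def test_empty_cohort_errors():
    with pytest.raises(ValueError, match="empty"):
        build_feature_table([])


def test_feature_count_invariant_to_phantom_parameters():
    cohorts = [
        generate_cohort(small_phantom_config(seed=1)),
        generate_cohort(
            small_phantom_config(
                seed=2,
                outer_semi_axes_mm=(26.0, 24.0, 22.0),
                inner_semi_axes_mm=(14.0, 13.0, 12.0),
            )
        ),
    ]
    for cohort in cohorts:
        fv = extract_features(cohort[0][0], ExtractionConfig(bin_width=5.0))
        assert len(fv.values) == 107
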