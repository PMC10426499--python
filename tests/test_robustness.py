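import numpy as np
import pandas as pd
import pytest

from radiostab.core import DegenerateFeatureError, VolumeWithMask
from radiostab.features.extractor import (
    CLASS_SHAPE,
    ExtractionConfig,
    feature_names,
)
from radiostab.phantom import ClassParams, generate_cohort
from radiostab.robustness import (
    RobustnessReport,
    TranslationSpec,
    icc,
    overlap_fraction,
    robustness_screen,
    screening_specs,
    translate_mask,
)
from tests.conftest import box_volume, small_phantom_config

# -- TranslationSpec --------------------------------------------------------


def test_spec_validation():
    TranslationSpec(0.005, "x")
    TranslationSpec(-0.30, "y")
    with pytest.raises(ValueError):
        TranslationSpec(0.1, "x")
    with pytest.raises(ValueError):
        TranslationSpec(0.30, "z")


def test_screening_specs_are_the_8_canonical_translations():
    specs = screening_specs()
    assert len(specs) == 8
    fr = sorted((s.fraction, s.axis) for s in specs)
    assert fr == sorted(
        [(f * s, ax) for f in (0.005, 0.30) for ax in ("x", "y") for s in (1, -1)]
    )


# -- translate_mask ---------------------------------------------------------


def test_zero_fraction_identity():
    v = box_volume()
    out = translate_mask(v, TranslationSpec(0.0, "x"))
    np.testing.assert_array_equal(out.mask, v.mask)


def test_30pct_of_40_voxel_box_is_12_voxels():
    v = box_volume(box=(40, 10, 10), shape=(80, 32, 32))
    out = translate_mask(v, TranslationSpec(0.30, "x"))
    assert out.mask.sum() == v.mask.sum()
    (lo0, _), _, _ = v.mask_bounding_box()
    (lo1, _), _, _ = out.mask_bounding_box()
    assert lo1 - lo0 == 12


def test_minimal_shift_floor_of_one_voxel():
    # 0.005 * 40 = 0.2 voxels -> floored up to 1
    v = box_volume(box=(40, 10, 10), shape=(80, 32, 32))
    out = translate_mask(v, TranslationSpec(0.005, "x"))
    (lo0, _), _, _ = v.mask_bounding_box()
    (lo1, _), _, _ = out.mask_bounding_box()
    assert lo1 - lo0 == 1


def test_translation_clipping_errors_with_subject_name():
    v = box_volume(box=(20, 10, 10), shape=(24, 32, 32))
    with pytest.raises(ValueError, match="subject s007"):
        translate_mask(v, TranslationSpec(0.30, "x"), subject="s007")


def test_intensities_untouched():
    v = box_volume()
    out = translate_mask(v, TranslationSpec(0.30, "y"))
    assert out.intensities is v.intensities


# -- overlap_fraction -------------------------------------------------------


def test_overlap_identity_100():
    v = box_volume()
    assert overlap_fraction(v.mask, v.mask) == 100.0


def test_overlap_disjoint_0():
    a = np.zeros((10, 10, 10), bool)
    b = np.zeros((10, 10, 10), bool)
    a[:2], b[8:] = True, True
    assert overlap_fraction(a, b) == 0.0


def test_overlap_half_shift_50pct_brute_force():
    v = box_volume(box=(10, 10, 10), shape=(40, 40, 40))
    out = translate_mask(v, TranslationSpec(0.30, "x"))  # 3 of 10 voxels
    brute = 100.0 * np.sum(v.mask & out.mask) / np.sum(v.mask)
    assert overlap_fraction(v.mask, out.mask) == pytest.approx(brute)
    assert brute == pytest.approx(70.0)


def test_overlap_empty_original_errors():
    with pytest.raises(ValueError, match="empty"):
        overlap_fraction(np.zeros((5, 5, 5), bool), np.ones((5, 5, 5), bool))


# -- icc --------------------------------------------------------------------


def test_icc_identical_vectors_is_one():
    a = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
    assert icc(a, a) == 1.0


def test_icc_toy_table_matches_frozen_oracle():
    # two-way random absolute-agreement single-measure ICC on the printed
    # 6-subject table; oracle frozen from an independent implementation
    a = np.arange(1.0, 7.0)
    assert icc(a, a + 100) == pytest.approx(0.0006995103427600679, abs=1e-9)


def test_icc_offset_well_below_one():
    a = np.arange(1.0, 7.0)
    assert icc(a, a + 100) < 0.01


def test_icc_independent_noise_near_zero():
    rng = np.random.default_rng(42)
    assert abs(icc(rng.standard_normal(1000), rng.standard_normal(1000))) < 0.1


def test_icc_symmetric():
    rng = np.random.default_rng(0)
    a, b = rng.standard_normal(50), rng.standard_normal(50)
    assert icc(a, b) == pytest.approx(icc(b, a), abs=1e-12)


def test_icc_invariant_to_common_affine_transform():
    rng = np.random.default_rng(1)
    a = rng.standard_normal(30)
    b = a + rng.normal(0, 0.5, 30)
    assert icc(2.5 * a - 7, 2.5 * b - 7) == pytest.approx(icc(a, b), abs=1e-10)


def test_icc_degenerate_cases():
    c = np.full(5, 3.0)
    assert icc(c, c) == 1.0
    with pytest.raises(DegenerateFeatureError):
        icc(c, c + 1.0)
    with pytest.raises(ValueError):
        icc(np.ones(2), np.ones(2))  # too short


# -- robustness_screen ------------------------------------------------------


@pytest.fixture(scope="module")
def screen_report():
    params = ClassParams(mean_hu=200.0, sd_hu=20.0, correlation_length_mm=2.0,
                         subject_mean_sd_hu=30.0)
    cfg = small_phantom_config(seed=21, n_per_class=3, class_params=(params, params))
    cohort = generate_cohort(cfg)
    return robustness_screen(cohort, ExtractionConfig(bin_width=2.0))


def test_screen_covers_the_93_nonshape_features(screen_report):
    assert len(screen_report.table) == 93
    assert not any(f.startswith(CLASS_SHAPE) for f in screen_report.table.index)


def test_shape_features_always_retained(screen_report):
    retained = set(screen_report.retained_features)
    assert set(feature_names((CLASS_SHAPE,))) <= retained


def test_stationary_field_mean_is_stable(screen_report):
    row = screen_report.table.loc["first-order/firstorder/Mean"]
    assert row["icc_min_mean"] > 0.75
    assert bool(row["stable"])


def test_maximal_translation_destroys_agreement_for_mean(screen_report):
    row = screen_report.table.loc["first-order/firstorder/Mean"]
    assert row["icc_max_mean"] < 0.5
    assert bool(row["discriminative"])


def test_screen_output_subset_of_input(screen_report):
    all_names = set(feature_names())
    assert set(screen_report.retained_features) <= all_names


def test_robust_equals_stable_and_discriminative(screen_report):
    t = screen_report.table
    ok = ~t.index.isin(screen_report.degenerate)
    pd.testing.assert_series_equal(
        t.loc[ok, "robust"], (t.loc[ok, "stable"] & t.loc[ok, "discriminative"]).rename("robust")
    )


def test_icc_values_within_clipped_range(screen_report):
    cols = [c for c in screen_report.table.columns if c.startswith("icc")]
    vals = screen_report.table[cols].to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    assert ((-1.0 <= vals) & (vals <= 1.0)).all()


def test_report_csv_roundtrip(tmp_path, screen_report):
    p = tmp_path / "report.csv"
    screen_report.to_csv(p)
    back = RobustnessReport.from_csv(p)
    pd.testing.assert_frame_equal(screen_report.table, back.table)
    assert back.retained_features[:14] == feature_names((CLASS_SHAPE,))


def test_injected_noise_feature_fails_stability():
    # replace one feature with fresh random noise per extraction by
    # simulating its per-translation values directly through the ICC path
    rng = np.random.default_rng(5)
    orig = rng.standard_normal(12)
    noisy_iccs = [icc(orig, rng.standard_normal(12)) for _ in range(4)]
    assert np.mean(noisy_iccs) < 0.75


def test_screen_needs_three_subjects():
    v = box_volume()
    with pytest.raises(ValueError, match="3 subjects"):
        robustness_screen([(v, 0), (v, 1)])
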