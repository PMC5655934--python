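"""Phantom realism, cohort ground truth, and generator determinism."""

import numpy as np
import pytest

from dxarfa import CohortSpec, LesionSpec, generate_cohort, repositioning_pair
from dxarfa.core import InputError, InvariantError
from dxarfa.synthetic import ZONE_NAMES, simulate_repositioning_study


def test_cancellous_core_values_in_expected_range(phantom):
    vals = phantom.scan.values[phantom.tissue_cores["cancellous"]]
    assert vals.size > 1000
    assert vals.min() >= 0.5 and vals.max() <= 1.0


def test_cortical_core_values_in_expected_range(phantom):
    vals = phantom.scan.values[phantom.tissue_cores["cortex"]]
    assert vals.size > 100
    assert vals.min() >= 2.0 and vals.max() <= 3.0


def test_prosthesis_region_reaches_stated_maximum(phantom):
    vals = phantom.scan.values[phantom.mask.prosthesis]
    assert vals.max() <= 4.0
    assert vals.min() >= 3.5


def test_foreground_pixel_count_matches_real_scan_size(phantom):
    n = int((phantom.mask.bone | phantom.mask.prosthesis).sum())
    assert 0.9 * 14000 <= n <= 1.1 * 14000


def test_phantom_landmarks_valid_and_zones_nonempty(phantom):
    phantom.landmarks.validate()
    assert set(ZONE_NAMES) <= set(phantom.zones)
    for name in ZONE_NAMES:
        assert phantom.zones[name].any(), name
        assert not (phantom.zones[name] & ~phantom.mask.bone).any(), name


def test_noise_free_lesion_free_cohort_is_longitudinally_constant():
    spec = CohortSpec(n_subjects=2, visit_months=(0, 12), lesions=(),
                      noise_sd_gcm2=0.0, shape_jitter_mm=1.0, rng_seed=3)
    cohort = generate_cohort(spec)
    for sid in cohort.subject_ids:
        a = cohort.scans[(sid, 0.0)].values
        b = cohort.scans[(sid, 12.0)].values
        assert np.array_equal(a, b)


def test_planted_lesion_is_exact_before_noise():
    lesion = LesionSpec(region="lesser_trochanter", magnitude_pct=-12.0,
                        target_area_fraction=0.15)
    spec = CohortSpec(n_subjects=2, visit_months=(0, 24), lesions=(lesion,),
                      noise_sd_gcm2=0.0, shape_jitter_mm=0.0, rng_seed=3)
    cohort = generate_cohort(spec)
    sid = cohort.subject_ids[0]
    fp = cohort.truth[sid].lesion_footprints[0]
    base = cohort.scans[(sid, 0.0)].values.astype(float)
    final = cohort.scans[(sid, 24.0)].values.astype(float)
    rel = (final[fp] - base[fp]) / base[fp]
    assert np.allclose(rel, -0.12, atol=1e-6)
    outside = ~fp
    assert np.array_equal(base[outside], final[outside])
    # footprint holds the requested fraction of bone pixels exactly
    n_bone = cohort.truth[sid].mask.bone.sum()
    assert fp.sum() == round(0.15 * n_bone)


def test_same_seed_gives_bitwise_identical_cohorts():
    spec = CohortSpec(n_subjects=3, visit_months=(0, 12), noise_sd_gcm2=0.05,
                      shape_jitter_mm=2.0, rng_seed=11)
    a = generate_cohort(spec)
    b = generate_cohort(spec)
    for key in a.scans:
        assert np.array_equal(a.scans[key].values, b.scans[key].values)
    for sid in a.truth:
        assert np.array_equal(a.truth[sid].mask.labels, b.truth[sid].mask.labels)


def test_lesion_time_profile_scales_mid_visits():
    lesion = LesionSpec(region="greater_trochanter", magnitude_pct=10.0,
                        target_area_fraction=0.1, time_profile=(0.0, 0.5, 1.0))
    spec = CohortSpec(n_subjects=2, visit_months=(0, 6, 24), lesions=(lesion,),
                      noise_sd_gcm2=0.0, shape_jitter_mm=0.0, rng_seed=1)
    cohort = generate_cohort(spec)
    sid = cohort.subject_ids[0]
    fp = cohort.truth[sid].lesion_footprints[0]
    base = cohort.scans[(sid, 0.0)].values.astype(float)
    mid = cohort.scans[(sid, 6.0)].values.astype(float)
    assert np.allclose((mid[fp] - base[fp]) / base[fp], 0.05, atol=1e-6)


def test_polygon_lesion_outside_bone_is_rejected(phantom):
    poly = np.array([[1.0, 1.0], [5.0, 1.0], [5.0, 5.0], [1.0, 5.0]])  # soft tissue
    lesion = LesionSpec(region=poly, magnitude_pct=-5.0, target_area_fraction=0.05)
    spec = CohortSpec(n_subjects=2, visit_months=(0, 12), lesions=(lesion,), rng_seed=0)
    with pytest.raises(InputError):
        generate_cohort(spec)


@pytest.mark.parametrize(
    "bad",
    [
        dict(n_subjects=1),
        dict(visit_months=(0, 12, 6)),
        dict(visit_months=(3, 6)),
        dict(noise_sd_gcm2=-0.1),
    ],
)
def test_cohort_spec_invariants(bad):
    kw = dict(n_subjects=3, visit_months=(0, 12))
    kw.update(bad)
    with pytest.raises(InvariantError):
        CohortSpec(**kw).validate()


def test_lesion_spec_time_profile_invariants():
    with pytest.raises(InvariantError):
        LesionSpec(region="diaphysis", magnitude_pct=-5, target_area_fraction=0.1,
                   time_profile=(0.2, 1.0)).validate()
    with pytest.raises(InvariantError):
        LesionSpec(region="diaphysis", magnitude_pct=-5,
                   target_area_fraction=1.5).validate()


def test_repositioning_pair_degenerate_case_is_identity(phantom, rng):
    a, b = repositioning_pair(phantom.scan, noise_sd_gcm2=0.0, rng=rng,
                              max_rot_deg=0.0, max_trans_mm=0.0)
    assert np.array_equal(a.values, phantom.scan.values)
    assert np.array_equal(a.values, b.values)


def test_repositioning_study_has_zero_true_change_and_29_pairs():
    cohort = simulate_repositioning_study(n_pairs=4, pixel_spacing_mm=0.94, rng_seed=5)
    assert len(cohort.subject_ids) == 4
    assert set(m for _, m in cohort.scans) == {0.0, 1.0}
    for tc in cohort.true_change.values():
        assert not tc.any()


def test_cohort_save_round_trip(tmp_path):
    from dxarfa.pipeline import load_cohort_dir

    spec = CohortSpec(n_subjects=2, visit_months=(0, 12), noise_sd_gcm2=0.05,
                      shape_jitter_mm=1.0, rng_seed=9, group_id="demo")
    cohort = generate_cohort(spec)
    cohort.save(tmp_path)
    scans = load_cohort_dir(tmp_path)
    assert len(scans) == 4
    key = ("S0", 0.0)
    assert np.array_equal(scans[key].values, cohort.scans[key].values)
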