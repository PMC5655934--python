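"""Landmark detection, GPA consensus, TPS fitting, and template warping."""

import numpy as np
import pytest

from dxarfa import (
    BMDScanRaster,
    CompartmentMask,
    LandmarkSet,
    detect_landmarks,
    gpa_consensus,
    gpa_template,
    segment_compartments,
    tps_fit,
    warp_to_template,
)
from dxarfa.core import LandmarkFailure
from dxarfa.registration import DegenerateLandmarksError, _align_similarity
from dxarfa.synthetic import _jittered_subject


def _rand_similarity(rng, pts):
    th = rng.uniform(0, 2 * np.pi)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return rng.uniform(0.5, 2.0) * pts @ rot.T + rng.uniform(-30, 30, 2)


# ---------------------------------------------------------------------------
# landmarks


def test_detected_landmarks_close_to_ground_truth(phantom, phantom_detected_landmarks):
    err = np.abs(phantom_detected_landmarks.points - phantom.landmarks.points)
    two_px_mm = 2 * phantom.scan.pixel_width_mm
    assert err.max() <= two_px_mm


def test_landmarks_mirror_under_laterality_flip(phantom, phantom_segmentation):
    width_mm = phantom.scan.shape[1] * phantom.scan.pixel_width_mm
    mirrored = BMDScanRaster(
        values=phantom.scan.values[:, ::-1].copy(),
        valid_mask=phantom.scan.valid_mask[:, ::-1].copy(),
        pixel_height_mm=phantom.scan.pixel_height_mm,
        pixel_width_mm=phantom.scan.pixel_width_mm,
        subject_id="m",
        visit_month=0,
        group_id="g",
        laterality="left",
    )
    mirrored_mask = CompartmentMask(labels=phantom_segmentation.labels[:, ::-1].copy())
    lm_left = detect_landmarks(mirrored, mirrored_mask)
    lm_right = detect_landmarks(phantom.scan, phantom_segmentation)
    flipped_back = lm_left.mirrored_x(width_mm)
    err = np.abs(flipped_back.points - lm_right.points)
    assert err.max() <= 2 * phantom.scan.pixel_width_mm


def test_mask_without_prosthesis_is_landmark_failure(phantom):
    labels = phantom.mask.labels.copy()
    labels[labels == 2] = 1
    with pytest.raises(LandmarkFailure):
        detect_landmarks(phantom.scan, CompartmentMask(labels=labels))


def test_landmark_set_rejects_coincident_points():
    pts = np.random.default_rng(0).uniform(0, 50, (16, 2))
    pts[5] = pts[3]
    with pytest.raises(Exception):
        LandmarkSet(points=pts).validate()


# ---------------------------------------------------------------------------
# GPA


def test_gpa_of_identical_sets_converges_immediately(rng):
    base = rng.uniform(0, 80, (16, 2))
    consensus, info = gpa_consensus([base.copy() for _ in range(5)])
    assert info["iterations"] <= 2
    bc = base - base.mean(0)
    bc /= np.linalg.norm(bc)
    assert np.linalg.norm(_align_similarity(consensus, bc) - bc) < 1e-9


def test_gpa_recovers_base_shape_under_20_random_similarities(rng):
    base = rng.uniform(0, 80, (16, 2))
    sets = [_rand_similarity(rng, base) for _ in range(20)]
    consensus, info = gpa_consensus(sets)
    assert info["converged"]
    bc = base - base.mean(0)
    bc /= np.linalg.norm(bc)
    assert np.linalg.norm(_align_similarity(consensus, bc) - bc) < 1e-6


def test_gpa_consensus_is_order_invariant(rng):
    sets = [rng.uniform(0, 80, (16, 2)) for _ in range(10)]
    c1, _ = gpa_consensus(sets, tol=1e-12, max_iter=500)
    perm = [sets[i] for i in rng.permutation(10)]
    c2, _ = gpa_consensus(perm, tol=1e-12, max_iter=500)
    assert np.abs(_align_similarity(c2, c1) - c1).max() < 1e-9


# ---------------------------------------------------------------------------
# TPS


def test_tps_identity_map_has_identity_affine_and_zero_weights(rng):
    src = rng.uniform(0, 80, (16, 2))
    tps = tps_fit(src, src)
    assert np.abs(tps.weights).max() < 1e-9
    assert np.abs(tps.affine[0]).max() < 1e-9
    assert np.abs(tps.affine[1:] - np.eye(2)).max() < 1e-9


def test_tps_recovers_pure_affine_with_zero_bending(rng):
    src = rng.uniform(0, 80, (16, 2))
    aff = np.array([[1.3, 0.2], [-0.1, 0.8]])
    tgt = src @ aff.T + np.array([4.0, -2.5])
    tps = tps_fit(src, tgt)
    assert np.abs(tps.weights).max() < 1e-9
    assert np.abs(tps(src) - tgt).max() < 1e-9


def test_tps_interpolates_every_landmark_exactly(rng):
    for _ in range(5):
        src = rng.uniform(0, 80, (16, 2))
        tgt = src + rng.normal(0, 5, (16, 2))
        tps = tps_fit(src, tgt)
        assert np.abs(tps(src) - tgt).max() < 1e-6


def test_tps_matches_scipy_thin_plate_rbf_off_landmarks(rng):
    from scipy.interpolate import RBFInterpolator

    src = rng.uniform(0, 80, (16, 2))
    tgt = src + rng.normal(0, 4, (16, 2))
    tps = tps_fit(src, tgt)
    query = rng.uniform(5, 75, (200, 2))
    ref = RBFInterpolator(src, tgt, kernel="thin_plate_spline", degree=1)
    assert np.abs(tps(query) - ref(query)).max() < 1e-6


def test_collinear_source_points_raise_rank_error():
    src = np.column_stack([np.linspace(0, 50, 16), np.linspace(0, 25, 16)])
    tgt = src + 1.0
    with pytest.raises(DegenerateLandmarksError):
        tps_fit(src, tgt)


# ---------------------------------------------------------------------------
# warping


def _self_template(phantom, landmarks):
    consensus = landmarks.points - landmarks.points.mean(0)
    consensus = consensus / np.linalg.norm(consensus)
    from dxarfa.registration import ShapeTemplate

    return ShapeTemplate(
        mean_landmarks=consensus,
        grid_landmarks_mm=landmarks.points,
        grid_shape=phantom.scan.shape,
        pixel_spacing_mm=phantom.scan.pixel_width_mm,
        template_bone_mask=phantom.mask.bone,
    )


def test_identity_warp_reproduces_bone_values(phantom):
    template = _self_template(phantom, phantom.landmarks)
    values, avail = warp_to_template(
        phantom.scan, phantom.mask, phantom.landmarks, template
    )
    assert avail.sum() > 0.9 * phantom.mask.bone.sum()
    assert np.abs(values[avail] - phantom.scan.values[avail]).max() < 1e-5


def test_warping_preserves_constant_bone_values(phantom):
    uniform = BMDScanRaster(
        values=np.where(phantom.mask.bone, 1.7, 0.0).astype(np.float32),
        valid_mask=np.ones(phantom.scan.shape, bool),
        pixel_height_mm=phantom.scan.pixel_height_mm,
        pixel_width_mm=phantom.scan.pixel_width_mm,
        subject_id="u",
        visit_month=0,
        group_id="g",
    )
    template = _self_template(phantom, phantom.landmarks)
    shifted = LandmarkSet(points=phantom.landmarks.points + np.array([1.7, -2.2]))
    values, avail = warp_to_template(uniform, phantom.mask, shifted, template)
    assert avail.any()
    assert np.abs(values[avail] - 1.7).max() < 1e-6


def test_deformed_phantom_warps_back_to_original(phantom, phantom_detected_landmarks):
    """End-to-end geometric recovery at the default 2 mm shape jitter.

    The mean absolute BMD discrepancy after detect→segment→TPS-warp is
    bounded by the registration accuracy the 16-landmark scheme delivers on
    a 0.56 mm grid (see docs/methods.md for the error budget).
    """
    template = _self_template(phantom, phantom_detected_landmarks)
    errs = []
    for seed in (0, 1, 2):
        rng = np.random.default_rng(seed)
        vals, labels, _ = _jittered_subject(phantom, (), 2.0, rng)
        scan_d = BMDScanRaster(
            values=vals.astype(np.float32),
            valid_mask=np.ones(vals.shape, bool),
            pixel_height_mm=phantom.scan.pixel_height_mm,
            pixel_width_mm=phantom.scan.pixel_width_mm,
            subject_id="d",
            visit_month=0,
            group_id="g",
        )
        seg = segment_compartments(scan_d)
        lm = detect_landmarks(scan_d, seg)
        values, avail = warp_to_template(scan_d, seg, lm, template)
        both = avail & phantom.mask.bone
        errs.append(np.abs(values[both] - phantom.scan.values[both]).mean())
    assert max(errs) < 0.12


def test_template_grid_covers_distal_shaft(phantom, phantom_detected_landmarks):
    template = gpa_template(
        [phantom_detected_landmarks, phantom.landmarks],
        pixel_spacing_mm=phantom.scan.pixel_width_mm,
    )
    grid_h_mm = template.grid_shape[0] * template.pixel_spacing_mm
    tip_y = template.grid_landmarks_mm[:, 1].max()
    assert grid_h_mm - tip_y > 20.0  # room for the shaft distal to the tip
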