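"""Landmark detection, Procrustes template construction, and TPS warping.

Every scan is reduced to an ordered set of K = 16 landmarks: four anatomic
points (prosthesis tip, prosthesis shoulder, greater-trochanter apex,
lesser-trochanter apex) and twelve control points on the medial and lateral
bone boundary at six evenly spaced heights between the prosthesis tip and
the greater-trochanter apex.  The ordering *is* the correspondence.

A per-group shape template is the Generalized Procrustes (GPA) consensus of
the baseline landmark configurations, placed on a pixel grid sized so the
consensus fits with a 10% margin.  Each scan is then warped onto the
template grid with an exact-interpolation thin-plate spline (kernel
U(r) = r^2 log r^2 plus an affine part) fitted from the template landmarks
to the scan landmarks, i.e. a backward mapping: every template pixel centre
is carried into the scan and the bone BMD is interpolated there.

BMD values are interpolated with bone-masked (normalised-convolution)
bilinear weights so that values from soft tissue or the prosthesis never
bleed into bone pixels, and constants over bone are preserved exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .core import (
    BONE,
    PROSTHESIS,
    BMDScanRaster,
    CompartmentMask,
    AnalysisConfig,
    InputError,
    InvariantError,
    LandmarkFailure,
)

__all__ = [
    "N_LANDMARKS",
    "LandmarkSet",
    "ShapeTemplate",
    "RegisteredCohortStack",
    "ScanRecord",
    "DegenerateLandmarksError",
    "detect_landmarks",
    "gpa_consensus",
    "gpa_template",
    "TPSTransform",
    "tps_fit",
    "warp_to_template",
    "build_stack",
    "register_cohort",
    "canonicalize_orientation",
]

N_LANDMARKS = 16
N_CONTROL_HEIGHTS = 6
_MIN_LANDMARK_SEP_MM = 0.5


class DegenerateLandmarksError(InvariantError):
    """Landmark configuration is rank deficient (e.g. collinear points)."""


@dataclass
class LandmarkSet:
    """Ordered 2D landmarks in scan millimetre coordinates.

    ``points`` is (K, 2) with columns (x_mm, y_mm); ``kinds`` labels each
    point ``anatomic`` or ``control``.
    """

    points: np.ndarray
    kinds: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if not self.kinds:
            self.kinds = ("anatomic",) * 4 + ("control",) * (len(self.points) - 4)

    def __len__(self) -> int:
        return len(self.points)

    def validate(self, expected_k: int = N_LANDMARKS) -> "LandmarkSet":
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise InvariantError("landmark points must be (K, 2)")
        if len(self.points) != expected_k:
            raise InvariantError(
                f"expected {expected_k} landmarks, got {len(self.points)}"
            )
        if not np.all(np.isfinite(self.points)):
            raise InvariantError("landmark coordinates must be finite")
        d = cdist(self.points, self.points)
        np.fill_diagonal(d, np.inf)
        if d.min() <= _MIN_LANDMARK_SEP_MM:
            raise InvariantError(
                f"landmarks coincide (min pairwise distance {d.min():.3g} mm)"
            )
        return self

    def mirrored_x(self, width_mm: float) -> "LandmarkSet":
        pts = self.points.copy()
        pts[:, 0] = width_mm - pts[:, 0]
        return LandmarkSet(points=pts, kinds=self.kinds)


# ---------------------------------------------------------------------------
# Landmark detection


_EDGE_THRESHOLD_GCM2 = 0.25


def _subpixel_edge(row_values: np.ndarray, col: int, direction: int) -> float:
    """Refine a bone-boundary column to subpixel precision.

    Linearly interpolates where the intensity profile crosses the bone
    threshold between the boundary pixel at ``col`` and its outside
    neighbour (``direction`` +1 for a lateral/min edge, −1 for medial/max).
    Falls back to the integer column when no informative crossing exists.
    """
    out = col - direction
    if not (0 <= out < row_values.size):
        return float(col)
    v_in, v_out = float(row_values[col]), float(row_values[out])
    if v_in <= _EDGE_THRESHOLD_GCM2 or v_out >= _EDGE_THRESHOLD_GCM2:
        return float(col)
    frac = (v_in - _EDGE_THRESHOLD_GCM2) / (v_in - v_out)  # in (0, 1]
    return float(col - direction * min(frac, 1.0))


def _outer_bone_boundary(labels: np.ndarray) -> np.ndarray:
    """Bone pixels on the outer silhouette boundary of bone ∪ prosthesis."""
    fg = (labels == BONE) | (labels == PROSTHESIS)
    interior = ndimage.binary_erosion(
        fg, structure=ndimage.generate_binary_structure(2, 1)
    )
    return (labels == BONE) & ~interior


def _prosthesis_axis_angle(labels: np.ndarray, ph: float, pw: float) -> float:
    """Tilt of the prosthesis stem's principal axis from vertical, radians."""
    r, c = np.nonzero(labels == PROSTHESIS)
    pts = np.column_stack([(c + 0.5) * pw, (r + 0.5) * ph])
    pts = pts - pts.mean(axis=0)
    cov = pts.T @ pts
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, np.argmax(evals)]  # (x, y) direction of the long axis
    if v[1] < 0:
        v = -v
    return float(np.arctan2(v[0], v[1]))


def _detect_once(
    labels: np.ndarray, values: np.ndarray, ph: float, pw: float
) -> np.ndarray:
    """One detection pass in the canonical right-hip orientation.

    Returns the (16, 2) landmark coordinates in mm.  The row-based
    definitions are applied in a prosthesis-aligned frame: the stem's
    principal axis is rotated to vertical first (scans are acquired with
    the stem near-vertical, so this is a small correction).
    """

    def to_mm(rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return np.column_stack(((cols + 0.5) * pw, (rows + 0.5) * ph))

    if not (labels == PROSTHESIS).any():
        raise LandmarkFailure("no prosthesis pixels; prosthesis landmarks undefined")
    if not (labels == BONE).any():
        raise LandmarkFailure("no bone pixels; bone landmarks undefined")

    # prosthesis-aligned frame: rotate the stem's principal axis to vertical
    theta = _prosthesis_axis_angle(labels, ph, pw)
    h_px, w_px = labels.shape
    center = np.array([w_px / 2.0 * pw, h_px / 2.0 * ph])
    if abs(theta) > np.deg2rad(0.05):
        cos_t, sin_t = np.cos(theta), np.sin(theta)
        rot_back = np.array([[cos_t, sin_t], [-sin_t, cos_t]])  # R(-theta)
        rr, cc = np.meshgrid(np.arange(h_px), np.arange(w_px), indexing="ij")
        q = np.column_stack(
            [((cc.ravel() + 0.5) * pw), ((rr.ravel() + 0.5) * ph)]
        )
        src = (q - center) @ rot_back.T + center
        coords = np.vstack([src[:, 1] / ph - 0.5, src[:, 0] / pw - 0.5])
        labels = ndimage.map_coordinates(labels, coords, order=0, cval=0).reshape(
            h_px, w_px
        )
        values = ndimage.map_coordinates(values, coords, order=1, cval=0.0).reshape(
            h_px, w_px
        )
        if not (labels == PROSTHESIS).any() or not (labels == BONE).any():
            raise LandmarkFailure("compartments lost during axis normalisation")
    else:
        theta = 0.0

    pros_r, pros_c = np.nonzero(labels == PROSTHESIS)
    bone_r, bone_c = np.nonzero(labels == BONE)

    # extreme-point landmarks are stabilised against pixel quantisation by
    # taking the centroid of the pixels within a small cap (~2 mm) at the
    # extremum, rather than a single extreme pixel
    cap_mm = 2.0
    pros_mm = to_mm(pros_r, pros_c)

    # prosthesis tip: most distal prosthesis pixels
    tip = pros_mm[pros_mm[:, 1] > pros_mm[:, 1].max() - cap_mm].mean(axis=0)

    # prosthesis shoulder: most proximal-lateral prosthesis pixels
    ps = pros_mm[:, 0] + pros_mm[:, 1]
    shoulder = pros_mm[ps < ps.min() + cap_mm].mean(axis=0)

    bnd_r, bnd_c = np.nonzero(_outer_bone_boundary(labels))
    if bnd_r.size == 0:
        raise LandmarkFailure("bone has no outer boundary pixels")
    bnd_mm = to_mm(bnd_r, bnd_c)

    # greater-trochanter apex: most proximal-lateral outer boundary points
    gs = bnd_mm[:, 0] + bnd_mm[:, 1]
    gt = bnd_mm[gs < gs.min() + cap_mm].mean(axis=0)

    # lesser-trochanter apex: most medially protruding boundary points in
    # the distal-medial quadrant (medial of the silhouette centroid, distal
    # of the prosthesis shoulder)
    fg = (labels == BONE) | (labels == PROSTHESIS)
    fr, fc = np.nonzero(fg)
    cx = (fc.mean() + 0.5) * pw
    quad = (bnd_mm[:, 0] > cx) & (bnd_mm[:, 1] > shoulder[1])
    if not quad.any():
        raise LandmarkFailure("no boundary points in the distal-medial quadrant")
    cand = bnd_mm[quad]
    lt = cand[cand[:, 0] > cand[:, 0].max() - cap_mm].mean(axis=0)

    # control points: medial and lateral bone boundary at 6 evenly spaced
    # heights strictly between the greater-trochanter apex and the tip; the
    # boundary column is averaged over a ±1.5 mm band of rows for stability
    bone_mask = labels == BONE
    anatomic = np.vstack([tip, shoulder, gt, lt])
    controls: list[np.ndarray] = []
    n_rows = labels.shape[0]
    band_px = max(1, int(round(1.5 / ph)))
    for k in range(1, N_CONTROL_HEIGHTS + 1):
        y_k = gt[1] + k * (tip[1] - gt[1]) / (N_CONTROL_HEIGHTS + 1)
        r0 = int(round(y_k / ph - 0.5))
        found = None
        for dr in (0, 1, -1, 2, -2, 3, -3):
            rows = [
                r
                for r in range(r0 + dr - band_px, r0 + dr + band_px + 1)
                if 0 <= r < n_rows and bone_mask[r].any()
            ]
            if not rows:
                continue
            lat_sub = []
            med_sub = []
            for r in rows:
                cols_r = np.nonzero(bone_mask[r])[0]
                lat_sub.append(_subpixel_edge(values[r], cols_r.min(), +1))
                med_sub.append(_subpixel_edge(values[r], cols_r.max(), -1))
            rows_arr = np.asarray(rows, dtype=float)
            lat = np.array(
                [
                    (np.mean(lat_sub) + 0.5) * pw,
                    (rows_arr.mean() + 0.5) * ph,
                ]
            )
            med = np.array(
                [
                    (np.mean(med_sub) + 0.5) * pw,
                    (rows_arr.mean() + 0.5) * ph,
                ]
            )
            # skip bands whose boundary points collide with an anatomic
            # landmark (e.g. the lesser-trochanter apex)
            sep = cdist(np.vstack([lat, med]), anatomic).min()
            if sep > _MIN_LANDMARK_SEP_MM:
                found = (lat, med)
                break
        if found is None:
            raise LandmarkFailure(f"no usable bone rows near control height {y_k:.1f} mm")
        controls.extend(found)

    pts = np.vstack([tip, shoulder, gt, lt] + controls)
    if theta != 0.0:
        # map back from the prosthesis-aligned frame to scan coordinates
        cos_t, sin_t = np.cos(theta), np.sin(theta)
        rot_back = np.array([[cos_t, sin_t], [-sin_t, cos_t]])
        pts = (pts - center) @ rot_back.T + center
    return pts


def detect_landmarks(scan: BMDScanRaster, mask: CompartmentMask) -> LandmarkSet:
    """Detect the fixed 16-point landmark set on one scan.

    Works in the canonical right-hip orientation (lateral aspect at small
    x); left-hip scans are mirrored internally and the coordinates mirrored
    back, so returned landmarks are always in the scan's own coordinates.

    Raises :class:`LandmarkFailure` if any landmark is undefined (e.g. the
    mask has no prosthesis pixels).
    """
    labels = mask.labels
    if scan.laterality == "left":
        flipped = CompartmentMask(labels=labels[:, ::-1])
        mirror_scan = BMDScanRaster(
            values=scan.values[:, ::-1],
            valid_mask=scan.valid_mask[:, ::-1],
            pixel_height_mm=scan.pixel_height_mm,
            pixel_width_mm=scan.pixel_width_mm,
            subject_id=scan.subject_id,
            visit_month=scan.visit_month,
            group_id=scan.group_id,
            laterality="right",
        )
        lm = detect_landmarks(mirror_scan, flipped)
        return lm.mirrored_x(scan.shape[1] * scan.pixel_width_mm)

    ph, pw = scan.pixel_height_mm, scan.pixel_width_mm
    values = np.where(scan.valid_mask, scan.values, 0.0).astype(float)
    pts = _detect_once(labels, values, ph, pw)
    kinds = ("anatomic",) * 4 + ("control",) * (2 * N_CONTROL_HEIGHTS)
    return LandmarkSet(points=pts, kinds=kinds).validate()


# ---------------------------------------------------------------------------
# Generalized Procrustes analysis


def _center(config: np.ndarray) -> np.ndarray:
    return config - config.mean(axis=0)


def _centroid_size(config: np.ndarray) -> float:
    return float(np.linalg.norm(_center(config)))


def _align_similarity(config: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares similarity (rotation + uniform scale) of a centered
    configuration onto a centered target.  Proper rotations only."""
    m = config.T @ target
    u, s, vt = np.linalg.svd(m)
    d = np.sign(np.linalg.det(u @ vt))
    diag = np.array([1.0, d])
    rot = (u * diag) @ vt
    scale = (s * diag).sum() / (config**2).sum()
    return scale * config @ rot


def gpa_consensus(
    landmark_sets: list[LandmarkSet] | list[np.ndarray],
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[np.ndarray, dict]:
    """Generalized Procrustes consensus of ≥2 landmark configurations.

    Iterates: align every configuration to the current consensus by a
    least-squares similarity transform, recompute the consensus as the mean,
    re-normalise it to zero centroid and unit centroid size; stop when the
    consensus moves less than ``tol``.  Returns the (K, 2) consensus and an
    info dict with iteration count, convergence flag and the mean centroid
    size of the inputs (the natural physical scale of the template).
    """
    configs = [
        np.asarray(ls.points if isinstance(ls, LandmarkSet) else ls, dtype=float)
        for ls in landmark_sets
    ]
    if len(configs) < 2:
        raise InputError("GPA requires at least 2 landmark configurations")
    k = configs[0].shape[0]
    if any(c.shape != (k, 2) for c in configs):
        raise InputError("all landmark configurations must share cardinality K")

    mean_cs = float(np.mean([_centroid_size(c) for c in configs]))
    centered = [_center(c) for c in configs]
    consensus = centered[0] / np.linalg.norm(centered[0])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        aligned = [_align_similarity(c, consensus) for c in centered]
        new = np.mean(aligned, axis=0)
        new = _center(new)
        new /= np.linalg.norm(new)
        shift = float(np.linalg.norm(new - consensus))
        consensus = new
        if shift < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"GPA did not converge within {max_iter} iterations", RuntimeWarning
        )
    return consensus, {
        "iterations": it,
        "converged": converged,
        "mean_centroid_size": mean_cs,
    }


@dataclass
class ShapeTemplate:
    """GPA mean shape plus the template pixel grid for one prosthesis type.

    ``mean_landmarks`` is the centred, unit-centroid-size consensus;
    ``grid_landmarks_mm`` is the same shape scaled to the cohort's mean
    centroid size and translated into the template grid's mm frame.
    ``template_bone_mask`` defines "all pixels in the template" for the
    areal statistics (majority vote of registered baseline bone masks).
    """

    mean_landmarks: np.ndarray
    grid_landmarks_mm: np.ndarray
    grid_shape: tuple[int, int]
    pixel_spacing_mm: float
    group_id: str = ""
    template_bone_mask: np.ndarray | None = None
    gpa_info: dict = field(default_factory=dict)

    def validate(self) -> "ShapeTemplate":
        if not np.allclose(self.mean_landmarks.mean(axis=0), 0, atol=1e-8):
            raise InvariantError("mean_landmarks must be centred at the origin")
        if not np.isclose(np.linalg.norm(self.mean_landmarks), 1.0, atol=1e-8):
            raise InvariantError("mean_landmarks must have unit centroid size")
        if self.template_bone_mask is not None and not self.template_bone_mask.any():
            raise InvariantError("template_bone_mask is empty")
        return self

    def pixel_centers_mm(self) -> tuple[np.ndarray, np.ndarray]:
        h, w = self.grid_shape
        y = (np.arange(h) + 0.5) * self.pixel_spacing_mm
        x = (np.arange(w) + 0.5) * self.pixel_spacing_mm
        return np.meshgrid(x, y)


def gpa_template(
    landmark_sets: list[LandmarkSet],
    pixel_spacing_mm: float,
    group_id: str = "",
    tol: float = 1e-6,
    max_iter: int = 100,
    margin_frac: float = 0.15,
    distal_margin_frac: float = 0.50,
) -> ShapeTemplate:
    """Build the shape template (without the bone-mask vote) from landmarks.

    The template grid is sized so the mean shape, at the cohort's mean
    centroid size, fits with a ``margin_frac`` margin, plus a larger distal
    margin: the landmarks span only the greater trochanter to the
    prosthesis tip, while the scanned field continues ~2.5 cm of femoral
    shaft distal to the tip, which the template must cover.
    """
    consensus, info = gpa_consensus(landmark_sets, tol=tol, max_iter=max_iter)
    phys = consensus * info["mean_centroid_size"]
    lo = phys.min(axis=0)
    hi = phys.max(axis=0)
    span = hi - lo
    margin = margin_frac * span
    grid_pts = phys - lo + margin
    extent = span + 2 * margin + np.array([0.0, (distal_margin_frac - margin_frac) * span[1]])
    grid_shape = (
        int(np.ceil(extent[1] / pixel_spacing_mm)),
        int(np.ceil(extent[0] / pixel_spacing_mm)),
    )
    return ShapeTemplate(
        mean_landmarks=consensus,
        grid_landmarks_mm=grid_pts,
        grid_shape=grid_shape,
        pixel_spacing_mm=pixel_spacing_mm,
        group_id=group_id,
        gpa_info=info,
    ).validate()


# ---------------------------------------------------------------------------
# Thin-plate spline


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    # U(r) = r^2 log r^2, with U(0) = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = r2 * np.log(r2)
    return np.where(r2 > 0, out, 0.0)


@dataclass
class TPSTransform:
    """Exact-interpolation thin-plate spline mapping R² → R².

    ``affine`` is (3, 2): rows are the constant, x and y coefficients;
    ``weights`` is (K, 2), one kernel weight per source landmark per output
    coordinate.
    """

    source: np.ndarray
    weights: np.ndarray
    affine: np.ndarray

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        k = _tps_kernel(cdist(pts, self.source, "sqeuclidean"))
        out = (
            self.affine[0]
            + pts @ self.affine[1:]
            + k @ self.weights
        )
        return out[0] if single else out

    @property
    def bending_weight_norm(self) -> float:
        return float(np.abs(self.weights).max())


def tps_fit(source: LandmarkSet | np.ndarray, target: LandmarkSet | np.ndarray) -> TPSTransform:
    """Fit the exact-interpolation TPS carrying ``source`` onto ``target``.

    No regularisation: the fitted map reproduces every source landmark's
    target exactly (to solver precision).  Raises
    :class:`DegenerateLandmarksError` when the source points are collinear.
    """
    src = np.asarray(source.points if isinstance(source, LandmarkSet) else source, float)
    tgt = np.asarray(target.points if isinstance(target, LandmarkSet) else target, float)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 2:
        raise InputError("source and target must be matching (K, 2) point sets")
    k = src.shape[0]
    if k < 3:
        raise DegenerateLandmarksError("TPS needs at least 3 source points")
    p = np.column_stack([np.ones(k), src])
    if np.linalg.matrix_rank(p, tol=1e-9 * max(1.0, np.abs(src).max())) < 3:
        raise DegenerateLandmarksError("source landmarks are collinear")
    kmat = _tps_kernel(cdist(src, src, "sqeuclidean"))
    lhs = np.zeros((k + 3, k + 3))
    lhs[:k, :k] = kmat
    lhs[:k, k:] = p
    lhs[k:, :k] = p.T
    rhs = np.zeros((k + 3, 2))
    rhs[:k] = tgt
    sol = np.linalg.solve(lhs, rhs)
    return TPSTransform(source=src, weights=sol[:k], affine=sol[k:])


# ---------------------------------------------------------------------------
# Warping and cohort stacks


def canonicalize_orientation(
    scan: BMDScanRaster, mask: CompartmentMask
) -> tuple[BMDScanRaster, CompartmentMask]:
    """Mirror a left-hip scan into the canonical right-hip orientation."""
    if scan.laterality == "right":
        return scan, mask
    return (
        BMDScanRaster(
            values=scan.values[:, ::-1].copy(),
            valid_mask=scan.valid_mask[:, ::-1].copy(),
            pixel_height_mm=scan.pixel_height_mm,
            pixel_width_mm=scan.pixel_width_mm,
            subject_id=scan.subject_id,
            visit_month=scan.visit_month,
            group_id=scan.group_id,
            laterality="right",
        ),
        CompartmentMask(labels=mask.labels[:, ::-1].copy()),
    )


def warp_to_template(
    scan: BMDScanRaster,
    mask: CompartmentMask,
    landmarks: LandmarkSet,
    template: ShapeTemplate,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample one scan's bone BMD onto the template grid.

    Backward mapping: a TPS fitted from the template landmarks to the scan
    landmarks carries every template pixel centre into the scan, where bone
    BMD is interpolated with bone-masked bilinear weights.  Returns
    ``(values, availability)`` on the template grid; a pixel is available
    only if it lands inside the scan, on the bone compartment
    (nearest-neighbour label), with positive bone support for interpolation.
    """
    tps = tps_fit(template.grid_landmarks_mm, landmarks.points)
    xg, yg = template.pixel_centers_mm()
    mapped = tps(np.column_stack([xg.ravel(), yg.ravel()]))
    rows = mapped[:, 1] / scan.pixel_height_mm - 0.5
    cols = mapped[:, 0] / scan.pixel_width_mm - 0.5
    h, w = scan.shape
    inside = (rows >= 0) & (rows <= h - 1) & (cols >= 0) & (cols <= w - 1)
    coords = np.vstack([rows, cols])

    weight = ((mask.labels == BONE) & scan.valid_mask).astype(float)
    num = ndimage.map_coordinates(scan.values * weight, coords, order=1, cval=0.0)
    den = ndimage.map_coordinates(weight, coords, order=1, cval=0.0)
    near_label = ndimage.map_coordinates(
        mask.labels, coords, order=0, mode="constant", cval=0
    )
    avail = inside & (near_label == BONE) & (den > 0.25)
    values = np.zeros(mapped.shape[0], dtype=np.float32)
    values[avail] = (num[avail] / den[avail]).astype(np.float32)
    return (
        values.reshape(template.grid_shape),
        avail.reshape(template.grid_shape),
    )


@dataclass
class ScanRecord:
    """One segmented, landmarked scan ready for registration."""

    subject_id: str
    visit_month: float
    scan: BMDScanRaster
    mask: CompartmentMask
    landmarks: LandmarkSet


@dataclass
class RegisteredCohortStack:
    """All subjects × visits resampled onto one template grid.

    ``values`` is (subjects, visits, rows, cols); ``availability`` flags
    pixels valid for a given subject/visit.  A pixel enters a paired test
    only if available at baseline AND at the follow-up visit being tested.
    """

    values: np.ndarray
    availability: np.ndarray
    subject_ids: tuple[str, ...]
    visit_months: tuple[float, ...]
    group_id: str
    template: ShapeTemplate

    def visit_index(self, month: float) -> int:
        try:
            return self.visit_months.index(float(month))
        except ValueError:
            raise InputError(
                f"visit month {month} not in stack (has {self.visit_months})"
            ) from None


def build_stack(
    records: list[ScanRecord],
    template: ShapeTemplate,
    baseline_visit: float = 0,
    log: list[str] | None = None,
) -> RegisteredCohortStack:
    """Warp every record onto the template and assemble the analysis stack.

    Subjects lacking the baseline visit are excluded (and logged); duplicate
    subject/visit pairs are an input error.  Availability is intersected
    with the template bone mask.
    """
    if template.template_bone_mask is None:
        raise InputError("template has no bone mask; build it from baselines first")
    seen: set[tuple[str, float]] = set()
    for rec in records:
        key = (rec.subject_id, float(rec.visit_month))
        if key in seen:
            raise InputError(f"duplicate subject/visit {key}")
        seen.add(key)

    months = sorted({float(r.visit_month) for r in records})
    by_subject: dict[str, dict[float, ScanRecord]] = {}
    for rec in records:
        by_subject.setdefault(rec.subject_id, {})[float(rec.visit_month)] = rec

    subjects = []
    for sid in sorted(by_subject):
        if float(baseline_visit) not in by_subject[sid]:
            if log is not None:
                log.append(f"excluded subject {sid}: missing baseline visit")
            continue
        subjects.append(sid)
    if not subjects:
        raise InputError("no subject has the baseline visit")

    h, w = template.grid_shape
    values = np.zeros((len(subjects), len(months), h, w), dtype=np.float32)
    avail = np.zeros((len(subjects), len(months), h, w), dtype=bool)
    tmask = template.template_bone_mask
    for i, sid in enumerate(subjects):
        for j, month in enumerate(months):
            rec = by_subject[sid].get(month)
            if rec is None:
                if log is not None:
                    log.append(f"subject {sid}: missing visit {month}")
                continue
            v, a = warp_to_template(rec.scan, rec.mask, rec.landmarks, template)
            values[i, j] = v
            avail[i, j] = a & tmask
    group = records[0].scan.group_id if records else ""
    return RegisteredCohortStack(
        values=values,
        availability=avail,
        subject_ids=tuple(subjects),
        visit_months=tuple(months),
        group_id=group,
        template=template,
    )


def register_cohort(
    records: list[ScanRecord],
    baseline_visit: float = 0,
    tol: float = 1e-6,
    max_iter: int = 100,
    log: list[str] | None = None,
) -> tuple[ShapeTemplate, RegisteredCohortStack]:
    """Template construction plus stack assembly for one prosthesis group.

    The template shape comes from GPA over the baseline landmark sets; the
    template bone mask is the ≥50% majority vote of the registered baseline
    bone masks.
    """
    base = [r for r in records if float(r.visit_month) == float(baseline_visit)]
    if len(base) < 2:
        raise InputError("need at least 2 baseline scans to build a template")
    spacing = base[0].scan.pixel_width_mm
    template = gpa_template(
        [r.landmarks for r in base],
        pixel_spacing_mm=spacing,
        group_id=base[0].scan.group_id,
        tol=tol,
        max_iter=max_iter,
    )
    votes = np.zeros(template.grid_shape, dtype=float)
    for rec in base:
        _, a = warp_to_template(rec.scan, rec.mask, rec.landmarks, template)
        votes += a
    template.template_bone_mask = votes >= 0.5 * len(base)
    template.validate()
    stack = build_stack(records, template, baseline_visit=baseline_visit, log=log)
    return template, stack
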