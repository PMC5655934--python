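"""Synthetic longitudinal periprosthetic DXA cohorts with known ground truth.

The generator emulates a post-operative proximal-femur DXA scan after total
hip arthroplasty: a femoral silhouette with cancellous trochanteric zones
(0.5–1 g/cm²), a cortical shaft (2–3 g/cm²), and a cemented stem whose
cement/prosthesis region reaches up to 4 g/cm², rasterised at 0.56 mm
isotropic pixels with roughly 14,000 pixels inside bone ∪ prosthesis.

A cohort is built from this phantom by giving each subject a smooth random
shape deformation (their anatomy, constant over visits), planting
multiplicative lesion fields that ramp up over visits, and adding i.i.d.
Gaussian pixel noise at each visit.  Every quantity the pipeline is later
asked to recover — the compartment mask, the landmark set, the per-visit
relative-change field — is retained as ground truth.

Nothing here attempts physical X-ray attenuation modelling; the phantom is
a geometric/densitometric stand-in whose value ranges and pixel counts match
descriptions of real periprosthetic scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .core import (
    BONE,
    PROSTHESIS,
    SOFT_TISSUE,
    BMDScanRaster,
    CompartmentMask,
    InputError,
    InvariantError,
    write_mask,
    write_scan,
)
from .registration import LandmarkSet, detect_landmarks

__all__ = [
    "ZONE_NAMES",
    "LesionSpec",
    "CohortSpec",
    "Phantom",
    "Cohort",
    "build_phantom",
    "make_phantom",
    "generate_cohort",
    "repositioning_pair",
    "simulate_repositioning_study",
]

# canonical phantom frame (mm); right hip, lateral aspect at small x
_H_MM = 105.0
_W_MM = 82.0
DEFAULT_PIXEL_MM = 0.56

ZONE_NAMES = (
    "lesser_trochanter",
    "greater_trochanter",
    "medial_cortex",
    "lateral_cortex",
    "diaphysis",
)


def _lateral_boundary(y: np.ndarray) -> np.ndarray:
    return 26.0 - 16.0 * np.exp(-(((y - 10.0) / 16.0) ** 2))


def _medial_boundary(y: np.ndarray) -> np.ndarray:
    return 66.0 + 10.0 * np.exp(-(((y - 40.0) / 16.0) ** 2))


def _neck_cut(x: np.ndarray) -> np.ndarray:
    # proximal resection line sloping distally on the medial side
    return 2.0 + 0.9 * np.maximum(0.0, x - 42.0)


def _stem_halfwidth(y: np.ndarray) -> np.ndarray:
    yc = np.clip(y, 18.0, 72.0)
    return 1.5 + 5.0 * (72.0 - yc) / 54.0


def _texture(x: np.ndarray, y: np.ndarray, phase: float = 0.0) -> np.ndarray:
    """Deterministic smooth field in [-1, 1] used for intra-compartment
    density variation (the phantom itself is noise-free)."""
    return np.cos(2 * np.pi * x / 23.0 + phase) * np.cos(2 * np.pi * y / 31.0 + 0.5 * phase)


@dataclass
class Phantom:
    """Canonical phantom: scan, true compartments, landmarks, named zones.

    ``tissue_cores`` holds the interior (partial-volume-free) cancellous and
    cortical masks on which the compartment value ranges hold per pixel.
    """

    scan: BMDScanRaster
    mask: CompartmentMask
    landmarks: LandmarkSet
    zones: dict[str, np.ndarray]
    tissue_cores: dict[str, np.ndarray] = field(default_factory=dict)


def build_phantom(pixel_spacing_mm: float = DEFAULT_PIXEL_MM) -> Phantom:
    """Rasterise the canonical proximal-femur phantom.

    Compartment value ranges follow typical post-operative baseline scans:
    cancellous 0.5–1 g/cm², cortical shaft 2–3 g/cm², stem/cement up to
    4 g/cm², soft tissue near 0.  At the default 0.56 mm pixels the
    bone ∪ prosthesis silhouette holds ≈14,000 pixels.
    """
    sp = float(pixel_spacing_mm)
    nrow = int(round(_H_MM / sp))
    ncol = int(round(_W_MM / sp))
    y = (np.arange(nrow) + 0.5)[:, None] * sp
    x = (np.arange(ncol) + 0.5)[None, :] * sp
    y = np.broadcast_to(y, (nrow, ncol))
    x = np.broadcast_to(x, (nrow, ncol))

    x_lat = _lateral_boundary(y)
    x_med = _medial_boundary(y)
    silhouette = (
        (x >= x_lat) & (x <= x_med) & (y >= _neck_cut(x)) & (y <= _H_MM - 2.0)
    )

    hw = _stem_halfwidth(y)
    stem = silhouette & (np.abs(x - 45.0) <= hw) & (y >= 18.0) & (y <= 72.0)
    cement = (
        silhouette
        & (np.abs(x - 45.0) <= hw + 2.5)
        & (y >= 15.5)
        & (y <= 74.5)
        & ~stem
    )
    prosthesis = stem | cement
    bone = silhouette & ~prosthesis

    cortex = bone & (y > 26.0) & (
        (x - x_lat < 4.0) | (x_med - x < 4.0) | (y > _H_MM - 6.0)
    )
    cancellous = bone & ~cortex

    t1 = _texture(x, y)
    t2 = _texture(x, y, phase=1.3)
    values = 0.06 + 0.04 * t1  # soft-tissue background, near zero
    values = np.where(cancellous, 0.75 + 0.20 * t1, values)
    values = np.where(cortex, 2.70 + 0.30 * t2, values)
    values = np.where(stem, 3.85 + 0.08 * t1, values)
    values = np.where(cement, 3.80 + 0.20 * t2, values)

    # partial-volume transition between cortical and cancellous bone: real
    # areal-BMD maps do not jump between compartments at a single pixel, so
    # values are smoothed *within* the bone compartment (masked Gaussian,
    # sigma 1.3 mm); compartment boundaries themselves stay sharp
    sigma_px = 1.3 / sp
    num = ndimage.gaussian_filter(np.where(bone, values, 0.0), sigma_px)
    den = ndimage.gaussian_filter(bone.astype(float), sigma_px)
    values = np.where(bone & (den > 1e-9), num / np.maximum(den, 1e-9), values)

    labels = np.full((nrow, ncol), SOFT_TISSUE, dtype=np.uint8)
    labels[bone] = BONE
    labels[prosthesis] = PROSTHESIS

    zones = {
        "greater_trochanter": bone & (y < 30.0) & (x < 38.0),
        "lesser_trochanter": bone & (y >= 28.0) & (y <= 52.0) & (x > 58.0),
        "lateral_cortex": bone & (x - x_lat < 3.0) & (y > 45.0),
        "medial_cortex": bone & (x_med - x < 3.0) & (y > 45.0),
        "diaphysis": bone & (y > 62.0),
    }

    # interiors on which the nominal compartment value ranges hold per pixel
    # (outside the partial-volume transition bands)
    canc_erode = max(1, int(np.ceil(2.8 / sp)))
    cort_erode = max(1, int(np.ceil(1.1 / sp)))
    tissue_cores = {
        "cancellous": ndimage.binary_erosion(cancellous, iterations=canc_erode),
        "cortex": ndimage.binary_erosion(cortex, iterations=cort_erode),
    }

    scan = BMDScanRaster(
        values=values.astype(np.float32),
        valid_mask=np.ones((nrow, ncol), dtype=bool),
        pixel_height_mm=sp,
        pixel_width_mm=sp,
        subject_id="phantom",
        visit_month=0,
        group_id="phantom",
        laterality="right",
    ).validate()
    mask = CompartmentMask(labels=labels).validate(scan)
    landmarks = detect_landmarks(scan, mask)
    return Phantom(
        scan=scan,
        mask=mask,
        landmarks=landmarks,
        zones=zones,
        tissue_cores=tissue_cores,
    )


def make_phantom(
    pixel_spacing_mm: float = DEFAULT_PIXEL_MM,
) -> tuple[BMDScanRaster, CompartmentMask, LandmarkSet]:
    """Return the canonical phantom as (scan, true mask, true landmarks)."""
    ph = build_phantom(pixel_spacing_mm)
    return ph.scan, ph.mask, ph.landmarks


# ---------------------------------------------------------------------------
# Lesions


@dataclass
class LesionSpec:
    """A planted longitudinal BMD change field.

    region
        Either a named template zone (one of :data:`ZONE_NAMES`) or an
        explicit (M, 2) polygon of (x_mm, y_mm) vertices in the canonical
        phantom frame.
    magnitude_pct
        Signed percent BMD change reached at the final visit (negative =
        bone loss).  The lesion acts multiplicatively: BMD is scaled by
        ``1 + magnitude_pct/100 × time_profile(visit)`` inside the region.
    time_profile
        Fraction of the final magnitude reached at each visit month, aligned
        with the cohort's ``visit_months``; must start at 0 and end at 1 and
        be non-decreasing in absolute value.  ``None`` means a linear ramp
        in months.
    target_area_fraction
        Intended fraction of bone pixels affected, in (0, 1).  The named
        zone (or polygon) is grown or shrunk by Euclidean distance until the
        footprint holds exactly that fraction of bone pixels.
    """

    region: str | np.ndarray
    magnitude_pct: float
    target_area_fraction: float
    time_profile: tuple[float, ...] | None = None

    def validate(self) -> "LesionSpec":
        if not (0 < self.target_area_fraction < 1):
            raise InvariantError(
                f"target_area_fraction must be in (0,1), got "
                f"{self.target_area_fraction}"
            )
        if self.time_profile is not None:
            prof = np.asarray(self.time_profile, float)
            if prof[0] != 0 or prof[-1] != 1:
                raise InvariantError("time_profile must start at 0 and end at 1")
            if np.any(np.diff(np.abs(prof)) < 0):
                raise InvariantError("time_profile must be non-decreasing in |value|")
        return self

    def profile_at(self, visit_months: tuple[float, ...]) -> np.ndarray:
        months = np.asarray(visit_months, float)
        if self.time_profile is None:
            span = months[-1] - months[0]
            return (months - months[0]) / span if span > 0 else np.zeros_like(months)
        prof = np.asarray(self.time_profile, float)
        if prof.shape != months.shape:
            raise InputError(
                "time_profile length must match the cohort's visit_months"
            )
        return prof


def _lesion_footprint(
    lesion: LesionSpec,
    bone: np.ndarray,
    zones: dict[str, np.ndarray],
    spacing_mm: float,
) -> np.ndarray:
    """Bone-pixel footprint holding the lesion's target area fraction.

    The seed region is grown/shrunk by signed Euclidean distance so the
    footprint holds exactly ``round(target_area_fraction × n_bone)`` pixels.
    """
    if isinstance(lesion.region, str):
        if lesion.region not in zones:
            raise InputError(
                f"unknown lesion zone {lesion.region!r}; known: {ZONE_NAMES}"
            )
        seed = zones[lesion.region]
    else:
        from skimage.draw import polygon2mask

        poly = np.asarray(lesion.region, float)
        rc = np.column_stack([poly[:, 1] / spacing_mm - 0.5, poly[:, 0] / spacing_mm - 0.5])
        seed = polygon2mask(bone.shape, rc)
        if seed.any() and np.any(seed & ~bone):
            raise InputError("lesion polygon extends outside the bone mask")
    if not (seed & bone).any():
        raise InputError("lesion region lies outside the bone mask")
    seed = seed & bone

    sampling = (spacing_mm, spacing_mm)
    signed = ndimage.distance_transform_edt(~seed, sampling=sampling) - (
        ndimage.distance_transform_edt(seed, sampling=sampling)
    )
    n_target = int(round(lesion.target_area_fraction * bone.sum()))
    flat_idx = np.flatnonzero(bone)
    order = np.argsort(signed.ravel()[flat_idx], kind="stable")
    footprint = np.zeros(bone.shape, dtype=bool)
    footprint.ravel()[flat_idx[order[:n_target]]] = True
    return footprint


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class CohortSpec:
    """Study conditions for one synthetic prosthesis group.

    Defaults mirror the cemented-stem trial arm: 35 subjects scanned at
    post-operative baseline and 3, 6, 12 and 24 months.
    """

    n_subjects: int = 35
    visit_months: tuple[float, ...] = (0, 3, 6, 12, 24)
    lesions: tuple[LesionSpec, ...] = ()
    noise_sd_gcm2: float = 0.05
    shape_jitter_mm: float = 2.0
    rng_seed: int = 0
    group_id: str = "synthetic"
    pixel_spacing_mm: float = DEFAULT_PIXEL_MM

    def validate(self) -> "CohortSpec":
        if self.n_subjects < 2:
            raise InvariantError("n_subjects must be >= 2")
        months = np.asarray(self.visit_months, float)
        if months.size < 1 or np.any(np.diff(months) <= 0):
            raise InvariantError("visit_months must be strictly increasing")
        if 0 not in months:
            raise InvariantError("visit_months must include the baseline month 0")
        if self.noise_sd_gcm2 < 0:
            raise InvariantError("noise_sd_gcm2 must be >= 0")
        for lesion in self.lesions:
            lesion.validate()
        return self


@dataclass
class SubjectTruth:
    """Per-subject ground truth (constant anatomy across visits)."""

    mask: CompartmentMask
    landmarks: LandmarkSet
    lesion_footprints: tuple[np.ndarray, ...]


@dataclass
class Cohort:
    """In-memory synthetic cohort with full ground truth."""

    spec: CohortSpec
    scans: dict[tuple[str, float], BMDScanRaster]
    truth: dict[str, SubjectTruth]
    true_change: dict[tuple[str, float], np.ndarray]

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.truth))

    def save(self, out_dir: str | Path) -> Path:
        """Write the cohort as group/subject/visit_<m>.tif(+.json) with
        ground-truth mask, landmarks and change fields alongside."""
        out = Path(out_dir)
        for (sid, month), scan in sorted(self.scans.items()):
            subj_dir = out / self.spec.group_id / sid
            write_scan(scan, subj_dir / f"visit_{_fmt_month(month)}.tif")
            tc = self.true_change[(sid, month)]
            import tifffile

            subj_dir.mkdir(parents=True, exist_ok=True)
            tifffile.imwrite(
                subj_dir / f"truth_change_{_fmt_month(month)}.tif",
                tc.astype(np.float32),
            )
        for sid, truth in self.truth.items():
            subj_dir = out / self.spec.group_id / sid
            write_mask(truth.mask, subj_dir / "truth_mask.tif")
            pts = truth.landmarks.points
            pd.DataFrame(
                {
                    "point_index": np.arange(len(pts)),
                    "kind": list(truth.landmarks.kinds),
                    "x_mm": pts[:, 0],
                    "y_mm": pts[:, 1],
                }
            ).to_csv(subj_dir / "truth_landmarks.csv", index=False)
        return out


def _fmt_month(month: float) -> str:
    return str(int(month)) if float(month).is_integer() else str(month)


def _subject_displacement(
    shape: tuple[int, int],
    spacing_mm: float,
    jitter_mm: float,
    rng: np.random.Generator,
    control_spacing_mm: float = 15.0,
) -> np.ndarray:
    """Random smooth anatomic deformation, returned as (2, H, W) backward
    displacements in mm (dy, dx).

    The field is a random affine part (small rotation, per-axis scale,
    shear, translation) — the dominant mode of subject-to-subject femoral
    shape variation — plus a low-amplitude smooth residual sampled on a
    coarse control grid (~15 mm spacing) and upsampled with a cubic spline.
    ``jitter_mm`` scales both parts; at the default 2 mm, typical total
    displacements over the femur are of the order of a couple of mm.
    """
    h, w = shape
    scale = jitter_mm / 2.0
    theta = rng.uniform(-1.5, 1.5) * scale * np.pi / 180.0
    log_s = rng.normal(0.0, 0.02 * scale, size=2)
    shear = rng.normal(0.0, 0.01 * scale)
    trans = rng.normal(0.0, jitter_mm / 2.0, size=2)  # (dx, dy)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    aff = rot @ np.array([[np.exp(log_s[0]), shear], [0.0, np.exp(log_s[1])]])
    center = np.array([w / 2.0, h / 2.0]) * spacing_mm

    yy = (np.arange(h) + 0.5) * spacing_mm
    xx = (np.arange(w) + 0.5) * spacing_mm
    py, px = np.meshgrid(yy, xx, indexing="ij")
    pts_xy = np.column_stack([px.ravel(), py.ravel()])
    src = (pts_xy - center - trans) @ np.linalg.inv(aff).T + center
    out = np.empty((2, h, w))
    out[0] = (src[:, 1] - pts_xy[:, 1]).reshape(h, w)
    out[1] = (src[:, 0] - pts_xy[:, 0]).reshape(h, w)

    resid_sd = 0.05 * jitter_mm
    if resid_sd > 0:
        ny = max(4, int(np.ceil(h * spacing_mm / control_spacing_mm)) + 1)
        nx = max(4, int(np.ceil(w * spacing_mm / control_spacing_mm)) + 1)
        yc = np.linspace(-0.5, h - 0.5, ny) * spacing_mm
        xc = np.linspace(-0.5, w - 0.5, nx) * spacing_mm
        coarse = rng.normal(0.0, resid_sd, size=(2, ny, nx))
        pts_yx = np.column_stack([py.ravel(), px.ravel()])
        for i in range(2):
            interp = RegularGridInterpolator(
                (yc, xc), coarse[i], method="cubic", bounds_error=False, fill_value=None
            )
            out[i] += interp(pts_yx).reshape(h, w)
    return out


def _resample_backward(
    values: np.ndarray,
    labels: np.ndarray,
    extra_masks: tuple[np.ndarray, ...],
    rows_src: np.ndarray,
    cols_src: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, tuple[np.ndarray, ...]]:
    coords = np.vstack([rows_src.ravel(), cols_src.ravel()])
    vals = ndimage.map_coordinates(values, coords, order=1, cval=0.0)
    labs = ndimage.map_coordinates(labels, coords, order=0, cval=SOFT_TISSUE)
    masks = tuple(
        ndimage.map_coordinates(m.astype(np.uint8), coords, order=0, cval=0).astype(
            bool
        ).reshape(values.shape)
        for m in extra_masks
    )
    return (
        vals.reshape(values.shape),
        labs.reshape(values.shape).astype(np.uint8),
        masks,
    )


def _jittered_subject(
    phantom: Phantom,
    footprints: tuple[np.ndarray, ...],
    jitter_mm: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, tuple[np.ndarray, ...]]:
    """One subject's anatomy: a smooth random deformation of the phantom."""
    scan = phantom.scan
    h, w = scan.shape
    if jitter_mm <= 0:
        return (
            scan.values.astype(float).copy(),
            phantom.mask.labels.copy(),
            tuple(f.copy() for f in footprints),
        )
    disp = _subject_displacement((h, w), scan.pixel_height_mm, jitter_mm, rng)
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    rows_src = rr + disp[0] / scan.pixel_height_mm
    cols_src = cc + disp[1] / scan.pixel_width_mm
    return _resample_backward(
        scan.values.astype(float), phantom.mask.labels, footprints, rows_src, cols_src
    )


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a fully ground-truthed longitudinal cohort.

    Per subject, a smooth random deformation of the phantom defines the
    anatomy, constant across visits.  At each visit, every lesion scales
    BMD multiplicatively inside its (subject-frame) footprint, then i.i.d.
    Gaussian noise is added and the result clipped at zero.  Identical
    specs (including the seed) give bitwise-identical cohorts.
    """
    spec.validate()
    phantom = build_phantom(spec.pixel_spacing_mm)
    bone = phantom.mask.bone
    footprints = tuple(
        _lesion_footprint(les, bone, phantom.zones, spec.pixel_spacing_mm)
        for les in spec.lesions
    )
    profiles = [les.profile_at(tuple(spec.visit_months)) for les in spec.lesions]

    rng = np.random.default_rng(spec.rng_seed)
    scans: dict[tuple[str, float], BMDScanRaster] = {}
    truth: dict[str, SubjectTruth] = {}
    true_change: dict[tuple[str, float], np.ndarray] = {}
    width = len(str(spec.n_subjects))
    for s in range(spec.n_subjects):
        sid = f"S{s:0{width}d}"
        base, labels, fps = _jittered_subject(
            phantom, footprints, spec.shape_jitter_mm, rng
        )
        mask_s = CompartmentMask(labels=labels)
        subject_scan = BMDScanRaster(
            values=base,
            valid_mask=np.ones_like(labels, dtype=bool),
            pixel_height_mm=spec.pixel_spacing_mm,
            pixel_width_mm=spec.pixel_spacing_mm,
            subject_id=sid,
            visit_month=0,
            group_id=spec.group_id,
        )
        landmarks_s = detect_landmarks(subject_scan, mask_s)
        truth[sid] = SubjectTruth(
            mask=mask_s, landmarks=landmarks_s, lesion_footprints=fps
        )
        for j, month in enumerate(spec.visit_months):
            factor = np.ones_like(base)
            for les, prof, fp in zip(spec.lesions, profiles, fps):
                factor = factor * np.where(
                    fp, 1.0 + les.magnitude_pct / 100.0 * prof[j], 1.0
                )
            clean = base * factor
            noisy = clean + rng.normal(0.0, spec.noise_sd_gcm2, size=base.shape)
            values = np.clip(noisy, 0.0, None) if spec.noise_sd_gcm2 > 0 else clean
            scans[(sid, float(month))] = BMDScanRaster(
                values=values.astype(np.float32),
                valid_mask=np.ones_like(labels, dtype=bool),
                pixel_height_mm=spec.pixel_spacing_mm,
                pixel_width_mm=spec.pixel_spacing_mm,
                subject_id=sid,
                visit_month=float(month),
                group_id=spec.group_id,
            ).validate()
            true_change[(sid, float(month))] = (factor - 1.0).astype(np.float32)
    return Cohort(spec=spec, scans=scans, truth=truth, true_change=true_change)


# ---------------------------------------------------------------------------
# Same-day repositioning (null experiment)


def _rigid_resample(
    values: np.ndarray,
    spacing_mm: float,
    rot_deg: float,
    shift_mm: tuple[float, float],
) -> np.ndarray:
    """Backward-map rigid motion (rotation about the grid centre, then
    translation) with bilinear interpolation; outside pixels become 0."""
    if rot_deg == 0 and shift_mm == (0.0, 0.0):
        return values.copy()
    h, w = values.shape
    theta = np.deg2rad(rot_deg)
    c, s = np.cos(theta), np.sin(theta)
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    out_pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float) - center
    shift_px = np.array(shift_mm) / spacing_mm
    rot_inv = np.array([[c, s], [-s, c]])
    src = (out_pts - shift_px) @ rot_inv.T + center
    res = ndimage.map_coordinates(values, src.T, order=1, cval=0.0)
    return res.reshape(h, w)


def repositioning_pair(
    subject_scan: BMDScanRaster,
    noise_sd_gcm2: float,
    rng: np.random.Generator,
    max_rot_deg: float = 2.0,
    max_trans_mm: float = 2.0,
) -> tuple[BMDScanRaster, BMDScanRaster]:
    """Two same-day scans of identical anatomy, repositioned independently.

    Each scan gets its own small rigid motion (rotation ≤ ``max_rot_deg``,
    translation ≤ ``max_trans_mm`` per axis) and an independent noise draw;
    the true BMD change between the pair is zero everywhere.
    """
    if noise_sd_gcm2 < 0:
        raise InvariantError("noise_sd_gcm2 must be >= 0")
    out = []
    for visit in (0.0, 1.0):
        if max_rot_deg > 0 or max_trans_mm > 0:
            rot = rng.uniform(-max_rot_deg, max_rot_deg)
            shift = tuple(rng.uniform(-max_trans_mm, max_trans_mm, size=2))
        else:
            rot, shift = 0.0, (0.0, 0.0)
        vals = _rigid_resample(
            subject_scan.values.astype(float),
            subject_scan.pixel_width_mm,
            rot,
            shift,
        )
        if noise_sd_gcm2 > 0:
            vals = np.clip(
                vals + rng.normal(0.0, noise_sd_gcm2, size=vals.shape), 0.0, None
            )
        out.append(
            BMDScanRaster(
                values=vals.astype(np.float32),
                valid_mask=np.ones_like(vals, dtype=bool),
                pixel_height_mm=subject_scan.pixel_height_mm,
                pixel_width_mm=subject_scan.pixel_width_mm,
                subject_id=subject_scan.subject_id,
                visit_month=visit,
                group_id=subject_scan.group_id,
                laterality=subject_scan.laterality,
            ).validate()
        )
    return out[0], out[1]


def simulate_repositioning_study(
    n_pairs: int = 29,
    noise_sd_gcm2: float = 0.05,
    shape_jitter_mm: float = 2.0,
    pixel_spacing_mm: float = DEFAULT_PIXEL_MM,
    rng_seed: int = 0,
    max_rot_deg: float = 2.0,
    max_trans_mm: float = 2.0,
) -> Cohort:
    """Simulate the same-day repositioning validation study.

    ``n_pairs`` subjects (29 in the validation experiment) are each scanned
    twice on the same day; the pair is encoded as pseudo-visits 0 and 1.
    True BMD change is zero everywhere, so any pixel the pipeline declares
    significant is a false discovery.
    """
    phantom = build_phantom(pixel_spacing_mm)
    rng = np.random.default_rng(rng_seed)
    spec = CohortSpec(
        n_subjects=max(2, n_pairs),
        visit_months=(0, 1),
        noise_sd_gcm2=noise_sd_gcm2,
        shape_jitter_mm=shape_jitter_mm,
        rng_seed=rng_seed,
        group_id="repositioning",
        pixel_spacing_mm=pixel_spacing_mm,
    )
    scans: dict[tuple[str, float], BMDScanRaster] = {}
    truth: dict[str, SubjectTruth] = {}
    true_change: dict[tuple[str, float], np.ndarray] = {}
    width = len(str(n_pairs))
    for s in range(n_pairs):
        sid = f"P{s:0{width}d}"
        base, labels, _ = _jittered_subject(phantom, (), shape_jitter_mm, rng)
        mask_s = CompartmentMask(labels=labels)
        subject_scan = BMDScanRaster(
            values=base,
            valid_mask=np.ones_like(labels, dtype=bool),
            pixel_height_mm=pixel_spacing_mm,
            pixel_width_mm=pixel_spacing_mm,
            subject_id=sid,
            visit_month=0,
            group_id=spec.group_id,
        )
        landmarks_s = detect_landmarks(subject_scan, mask_s)
        truth[sid] = SubjectTruth(mask=mask_s, landmarks=landmarks_s, lesion_footprints=())
        a, b = repositioning_pair(
            subject_scan,
            noise_sd_gcm2,
            rng,
            max_rot_deg=max_rot_deg,
            max_trans_mm=max_trans_mm,
        )
        scans[(sid, 0.0)] = a
        scans[(sid, 1.0)] = b
        zero = np.zeros(base.shape, dtype=np.float32)
        true_change[(sid, 0.0)] = zero
        true_change[(sid, 1.0)] = zero
    return Cohort(spec=spec, scans=scans, truth=truth, true_change=true_change)
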