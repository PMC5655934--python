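"""Domain types, coordinate conventions, and scan I/O.

Conventions used throughout the package
---------------------------------------
* Rasters are 2D arrays indexed ``(row, column)``, 0-based.  Row 0 is the
  proximal (superior) edge of the scan; rows increase distally.
* Physical coordinates are millimetres.  A pixel ``(r, c)`` has its centre at
  ``y = (r + 0.5) * pixel_height_mm``, ``x = (c + 0.5) * pixel_width_mm``.
  Landmarks and all registration maths live in these (x, y) mm coordinates.
* Laterality: the canonical orientation is a *right* hip, with the lateral
  aspect (greater trochanter) at small x.  Left-hip scans are mirrored into
  this frame before registration.

On disk a scan is a 32-bit float single-channel TIFF plus a JSON sidecar
carrying the pixel spacing and subject/visit/group metadata.  Invalid
(unmeasured) pixels are stored as NaN.  Compartment masks are 8-bit TIFFs
with integer codes 0/1/2 = soft tissue / bone / prosthesis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "SOFT_TISSUE",
    "BONE",
    "PROSTHESIS",
    "RFAError",
    "MetadataError",
    "FormatError",
    "InvariantError",
    "ConfigError",
    "InputError",
    "SegmentationFailure",
    "LandmarkFailure",
    "BMDScanRaster",
    "CompartmentMask",
    "AnalysisConfig",
    "read_scan",
    "write_scan",
    "read_mask",
    "write_mask",
]

SOFT_TISSUE = 0
BONE = 1
PROSTHESIS = 2

_LATERALITIES = ("left", "right")


class RFAError(Exception):
    """Base class for all errors raised by this package."""


class MetadataError(RFAError):
    """A sidecar is missing or lacks required metadata."""


class FormatError(RFAError):
    """An on-disk artefact violates the declared format."""


class InvariantError(RFAError):
    """An in-memory object violates a type invariant."""


class ConfigError(RFAError):
    """A configuration value is invalid; the message names the field."""


class InputError(RFAError):
    """Inconsistent inputs to a pipeline stage (e.g. duplicate visits)."""


class SegmentationFailure(RFAError):
    """Segmentation produced an empty bone compartment."""


class LandmarkFailure(RFAError):
    """A required landmark is undefined for this scan."""


@dataclass
class BMDScanRaster:
    """One areal-BMD raster scan (g/cm²) with its acquisition metadata.

    ``values`` holds areal bone mineral density per pixel; ``valid_mask``
    flags pixels that were actually measured.  Invalid pixels carry no
    meaningful value and are excluded from every downstream computation.
    """

    values: np.ndarray
    valid_mask: np.ndarray
    pixel_height_mm: float
    pixel_width_mm: float
    subject_id: str
    visit_month: float
    group_id: str
    laterality: str = "right"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def validate(self) -> "BMDScanRaster":
        """Check all type invariants; raise :class:`InvariantError` on failure."""
        if self.values.ndim != 2:
            raise InvariantError("values must be a 2D grid")
        if self.values.shape != self.valid_mask.shape:
            raise InvariantError(
                f"values grid {self.values.shape} and valid_mask grid "
                f"{self.valid_mask.shape} have different dimensions"
            )
        if not (self.pixel_height_mm > 0 and self.pixel_width_mm > 0):
            raise InvariantError("pixel spacing must be positive")
        vals = self.values[self.valid_mask]
        if vals.size and (not np.all(np.isfinite(vals)) or np.any(vals < 0)):
            raise InvariantError("valid pixels must hold finite, non-negative BMD")
        if self.visit_month < 0:
            raise InvariantError("visit_month must be non-negative")
        if self.laterality not in _LATERALITIES:
            raise InvariantError(f"laterality must be one of {_LATERALITIES}")
        return self

    def pixel_centers_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) mm coordinates of every pixel centre."""
        h, w = self.shape
        y = (np.arange(h) + 0.5) * self.pixel_height_mm
        x = (np.arange(w) + 0.5) * self.pixel_width_mm
        return np.meshgrid(x, y)


@dataclass
class CompartmentMask:
    """Per-pixel compartment labels {soft_tissue=0, bone=1, prosthesis=2}."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def bone(self) -> np.ndarray:
        return self.labels == BONE

    @property
    def prosthesis(self) -> np.ndarray:
        return self.labels == PROSTHESIS

    @property
    def soft_tissue(self) -> np.ndarray:
        return self.labels == SOFT_TISSUE

    def validate(self, scan: BMDScanRaster | None = None) -> "CompartmentMask":
        if self.labels.ndim != 2:
            raise InvariantError("labels must be a 2D grid")
        if not np.isin(self.labels, (SOFT_TISSUE, BONE, PROSTHESIS)).all():
            raise InvariantError("labels must be in {0, 1, 2}")
        if scan is not None and self.labels.shape != scan.shape:
            raise FormatError(
                f"mask dimensions {self.labels.shape} do not match raster "
                f"{scan.shape}"
            )
        return self

    def component_counts(self) -> dict[str, int]:
        """Number of connected components per non-background compartment."""
        from skimage.measure import label as cc_label

        return {
            "bone": int(cc_label(self.bone, connectivity=2).max()),
            "prosthesis": int(cc_label(self.prosthesis, connectivity=2).max()),
        }


@dataclass
class AnalysisConfig:
    """Statistical analysis settings.

    alpha
        FDR level for Benjamini–Hochberg selection (default 0.05).
    baseline_visit
        Month index of the post-operative baseline scan (default 0).
    min_subjects_per_pixel
        A pixel is tested only if at least this many subjects contribute a
        paired difference there (default 5); pixels below the minimum are
        excluded from the multiple-testing count N.
    rng_seed
        Seed for any stochastic step run under this configuration.
    """

    alpha: float = 0.05
    baseline_visit: float = 0
    min_subjects_per_pixel: int = 5
    rng_seed: int = 0

    def validate(self) -> "AnalysisConfig":
        if not (0 < self.alpha < 1):
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.min_subjects_per_pixel < 2:
            raise ConfigError(
                f"min_subjects_per_pixel must be >= 2, got "
                f"{self.min_subjects_per_pixel}"
            )
        if self.baseline_visit < 0:
            raise ConfigError(
                f"baseline_visit must be non-negative, got {self.baseline_visit}"
            )
        return self


# ---------------------------------------------------------------------------
# Scan and mask I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_scan(scan: BMDScanRaster, path: str | Path) -> None:
    """Write a scan as float32 TIFF + JSON sidecar (see module docstring)."""
    scan.validate()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    values = scan.values.astype(np.float32).copy()
    values[~scan.valid_mask] = np.nan
    tifffile.imwrite(path, values)
    meta = {
        "pixel_height_mm": float(scan.pixel_height_mm),
        "pixel_width_mm": float(scan.pixel_width_mm),
        "subject_id": scan.subject_id,
        "visit_month": float(scan.visit_month),
        "group_id": scan.group_id,
        "laterality": scan.laterality,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_scan(path: str | Path) -> BMDScanRaster:
    """Read a scan written by :func:`write_scan`.

    Non-finite pixels become invalid in ``valid_mask``.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MetadataError(f"missing sidecar {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:  # pragma: no cover - defensive
        raise MetadataError(f"unreadable sidecar {sidecar}: {exc}") from exc
    required = {
        "pixel_height_mm",
        "pixel_width_mm",
        "subject_id",
        "visit_month",
        "group_id",
        "laterality",
    }
    missing = required - meta.keys()
    if missing:
        raise MetadataError(f"sidecar {sidecar} lacks fields {sorted(missing)}")
    values = np.asarray(tifffile.imread(path), dtype=np.float32)
    if values.ndim != 2:
        raise FormatError(f"{path} is not a single-channel 2D raster")
    valid = np.isfinite(values)
    values = np.where(valid, values, 0.0).astype(np.float32)
    scan = BMDScanRaster(
        values=values,
        valid_mask=valid,
        pixel_height_mm=meta["pixel_height_mm"],
        pixel_width_mm=meta["pixel_width_mm"],
        subject_id=str(meta["subject_id"]),
        visit_month=float(meta["visit_month"]),
        group_id=str(meta["group_id"]),
        laterality=str(meta["laterality"]),
    )
    try:
        return scan.validate()
    except InvariantError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_mask(mask: CompartmentMask, path: str | Path, scan: BMDScanRaster | None = None) -> None:
    """Write a compartment mask as an 8-bit TIFF with codes 0/1/2."""
    mask.validate(scan)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, mask.labels.astype(np.uint8))


def read_mask(path: str | Path, scan: BMDScanRaster | None = None) -> CompartmentMask:
    labels = np.asarray(tifffile.imread(Path(path)))
    mask = CompartmentMask(labels=labels)
    try:
        return mask.validate(scan)
    except InvariantError as exc:
        raise FormatError(f"{path}: {exc}") from exc
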