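"""Compartment segmentation: prosthesis, bone, and soft tissue.

The pipeline is intensity thresholding refined by an edge map, followed by
morphological cleanup, in a fixed order:

1. a Gaussian-smoothed gradient-magnitude edge map at scale ``edge_sigma_px``
   refines the threshold boundaries (pixels on strong edges are classified
   by their raw value; elsewhere the smoothed value is thresholded, which
   suppresses isolated noise),
2. threshold at ``prosthesis_threshold_gcm2`` → prosthesis candidates,
3. threshold at ``bone_threshold_gcm2`` on the remaining pixels → bone
   candidates,
4. morphological opening then closing (disk of radius ``morph_radius_px``)
   on each candidate mask,
5. connected components smaller than ``min_component_px`` are dropped,
6. holes in the prosthesis mask are filled.

Everything left is soft tissue.  Scans whose bone compartment comes out
empty are rejected with :class:`~dxarfa.core.SegmentationFailure` — they are
excluded and logged, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, morphology

from .core import (
    BONE,
    PROSTHESIS,
    SOFT_TISSUE,
    BMDScanRaster,
    CompartmentMask,
    InvariantError,
    SegmentationFailure,
)

__all__ = ["SegmentationParams", "segment_compartments"]


@dataclass
class SegmentationParams:
    """Segmentation thresholds and cleanup scales.

    The operator classes (edge detection, intensity thresholds, morphology)
    are fixed; the numeric values are package defaults, declared here so
    runs are reproducible, and exposed in the run configuration.
    """

    prosthesis_threshold_gcm2: float = 3.5
    bone_threshold_gcm2: float = 0.25
    edge_sigma_px: float = 1.5
    morph_radius_px: int = 2
    min_component_px: int = 50

    def validate(self) -> "SegmentationParams":
        if not (0 < self.bone_threshold_gcm2 < self.prosthesis_threshold_gcm2):
            raise InvariantError(
                "need 0 < bone_threshold_gcm2 < prosthesis_threshold_gcm2"
            )
        if self.morph_radius_px < 0:
            raise InvariantError("morph_radius_px must be >= 0")
        if self.min_component_px < 1:
            raise InvariantError("min_component_px must be >= 1")
        return self


def _drop_small_components(mask: np.ndarray, min_px: int) -> np.ndarray:
    labelled, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return mask
    sizes = np.bincount(labelled.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[labelled]


def _cleanup(mask: np.ndarray, params: SegmentationParams) -> np.ndarray:
    if params.morph_radius_px > 0:
        footprint = morphology.disk(params.morph_radius_px)
        mask = ndimage.binary_opening(mask, structure=footprint)
        mask = ndimage.binary_closing(mask, structure=footprint)
    if params.min_component_px > 1:
        mask = _drop_small_components(mask, params.min_component_px)
    return mask


def segment_compartments(
    scan: BMDScanRaster, params: SegmentationParams | None = None
) -> CompartmentMask:
    """Partition a scan into prosthesis, bone, and soft-tissue compartments.

    Deterministic: re-running on the same input yields an identical mask.
    Raises :class:`SegmentationFailure` if no bone pixels survive cleanup.
    """
    params = (params or SegmentationParams()).validate()
    scan.validate()
    values = np.where(scan.valid_mask, scan.values, 0.0).astype(float)

    smoothed = filters.gaussian(values, sigma=params.edge_sigma_px, preserve_range=True)
    edge_map = filters.sobel(smoothed)
    # boundary refinement: on strong edges trust the raw pixel, elsewhere the
    # smoothed one (thresholding the latter suppresses isolated noise)
    strong_edge = edge_map > 0.15 * edge_map.max() if edge_map.max() > 0 else np.zeros_like(edge_map, bool)
    field = np.where(strong_edge, values, smoothed)

    pros = field >= params.prosthesis_threshold_gcm2
    bone = (field >= params.bone_threshold_gcm2) & ~pros

    pros = _cleanup(pros, params)
    bone = _cleanup(bone, params) & ~pros
    pros = ndimage.binary_fill_holes(pros)
    bone = bone & ~pros

    if not bone.any():
        raise SegmentationFailure(
            f"no bone pixels after cleanup for subject {scan.subject_id}, "
            f"visit {scan.visit_month}"
        )

    labels = np.full(scan.shape, SOFT_TISSUE, dtype=np.uint8)
    labels[bone] = BONE
    labels[pros] = PROSTHESIS
    labels[~scan.valid_mask] = SOFT_TISSUE
    return CompartmentMask(labels=labels).validate(scan)
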