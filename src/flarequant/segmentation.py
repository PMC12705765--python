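"""Cell masks and the PM-ring / cytoplasm ROIs derived from them.

External masks (from any segmenter) are the primary path; a classical
fallback (smooth, threshold, fill, distance-transform watershed) exists so
that synthetic images can be segmented without a learned model. All 2-D
morphology uses 8-connectivity and disk structuring elements.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, morphology, segmentation as sk_seg
from skimage.feature import peak_local_max

from .types import CellROIs, LabelMask

__all__ = [
    "segment_cells",
    "exclude_border_cells",
    "make_rois",
    "match_labels_by_overlap",
]

logger = logging.getLogger(__name__)

DEFAULT_RING_WIDTH_PX = 3
DEFAULT_EROSION_DEPTH_PX = 6


def remove_small(arr: np.ndarray, min_area_px: int, connectivity: int = 2) -> np.ndarray:
    """Drop connected components (bool input) or labels smaller than min_area_px."""
    if arr.dtype == bool:
        labels, _ = ndi.label(arr, structure=np.ones((3, 3)) if connectivity == 2 else None)
        areas = np.bincount(labels.ravel())
        return arr & (areas[labels] >= min_area_px)
    areas = np.bincount(arr.ravel())
    out = arr.copy()
    out[(areas[arr] < min_area_px) & (arr > 0)] = 0
    return out


def segment_cells(
    image: np.ndarray,
    sigma_px: float = 2.0,
    min_area_px: int = 100,
    min_distance_px: int = 15,
    pixel_size_um: float = 0.1,
) -> LabelMask:
    """Threshold-and-watershed segmentation of a single-channel 2-D image.

    Smooths with a Gaussian, thresholds with Otsu, fills holes (cells imaged
    at the equatorial plane are rings with dimmer interiors), then splits
    touching cells by watershed on the distance transform seeded at its
    local maxima.
    """
    image = np.asarray(image, float)
    if image.ndim != 2:
        raise ValueError("segment_cells expects a single-channel 2-D image")
    if image.size == 0:
        raise ValueError("empty image")

    smoothed = filters.gaussian(image, sigma=sigma_px, preserve_range=True)
    if np.ptp(smoothed) == 0:
        logger.warning("flat image: no cells segmented")
        return LabelMask(np.zeros(image.shape, np.uint16), pixel_size_um)
    fg = smoothed > filters.threshold_otsu(smoothed)
    fg = ndi.binary_fill_holes(fg)
    # smoothing spreads the bright PM ring outward by ~sigma; shrink back
    comp = int(round(sigma_px))
    if comp >= 1:
        fg = ndi.binary_erosion(fg, structure=morphology.disk(comp), border_value=0)
    fg = remove_small(fg, min_area_px)
    if not fg.any():
        logger.warning("all-background segmentation result")
        return LabelMask(np.zeros(image.shape, np.uint16), pixel_size_um)

    dist = ndi.distance_transform_edt(fg)
    peaks = peak_local_max(dist, min_distance=min_distance_px, labels=fg)
    markers = np.zeros(image.shape, np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        labels = ndi.label(fg, structure=np.ones((3, 3)))[0]
    else:
        labels = sk_seg.watershed(-dist, markers, mask=fg, connectivity=2)
    labels = remove_small(labels, min_area_px)
    return LabelMask(labels.astype(np.uint16), pixel_size_um)


def exclude_border_cells(mask: LabelMask) -> LabelMask:
    """Remove every cell with at least one pixel on the image border.

    Surviving ids are unchanged. Idempotent.
    """
    data = mask.data
    border_ids = np.unique(
        np.concatenate([data[0], data[-1], data[:, 0], data[:, -1]])
    )
    border_ids = border_ids[border_ids > 0]
    if border_ids.size == 0:
        return LabelMask(data.copy(), mask.pixel_size_um)
    out = data.copy()
    out[np.isin(out, border_ids)] = 0
    logger.info("excluded %d border cell(s)", border_ids.size)
    return LabelMask(out, mask.pixel_size_um)


def make_rois(
    mask: LabelMask,
    ring_width_px: int = DEFAULT_RING_WIDTH_PX,
    erosion_depth_px: int = DEFAULT_EROSION_DEPTH_PX,
) -> list[CellROIs]:
    """Ring-shaped peripheral ROI and eroded internal ROI for every cell.

    ``pm_ring = cell - erode(cell, ring_width)`` and
    ``cytoplasm = erode(cell, erosion_depth)``; with
    ``erosion_depth >= ring_width`` the two are disjoint. Cells eroded away
    entirely (slivers thinner than the ring) are dropped with a logged
    reason rather than returned degenerate.
    """
    if ring_width_px < 1:
        raise ValueError("ring_width_px must be >= 1")
    if erosion_depth_px < ring_width_px:
        raise ValueError("erosion_depth_px must be >= ring_width_px")
    ring_se = morphology.disk(ring_width_px)
    cyto_se = morphology.disk(erosion_depth_px)

    rois: list[CellROIs] = []
    for label in mask.labels:
        cell = mask.cell(int(label))
        inner = ndi.binary_erosion(cell, structure=ring_se, border_value=0)
        ring = cell & ~inner
        cyto = ndi.binary_erosion(cell, structure=cyto_se, border_value=0)
        if not ring.any() or not cyto.any():
            logger.info("cell %d dropped: fully eroded at ring=%d/depth=%d px",
                        label, ring_width_px, erosion_depth_px)
            continue
        rois.append(CellROIs(int(label), ring, cyto, ring_width_px, erosion_depth_px))
    return rois


def match_labels_by_overlap(reference: LabelMask, other: LabelMask) -> dict[int, int]:
    """Map each reference id to the other mask's id of maximal pixel overlap.

    A utility for matching per-frame masks; ids with no overlapping foreground
    are omitted.
    """
    mapping: dict[int, int] = {}
    for label in reference.labels:
        overlap = other.data[reference.cell(int(label))]
        overlap = overlap[overlap > 0]
        if overlap.size:
            vals, counts = np.unique(overlap, return_counts=True)
            mapping[int(label)] = int(vals[np.argmax(counts)])
    return mapping
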