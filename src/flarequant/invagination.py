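"""High-content quantification of PM invaginations.

The reference-reporter image is enhanced with a white top-hat (image minus
its morphological opening), which keeps bright structures thinner than the
structuring element and zeroes flat regions. Invaginations are then
segmented per cell in the cell interior (the peripheral PM ring itself is
excluded — invaginations are inward structures), the invagination area is
normalized to the cell area, averaged per condition and timepoint, and
finally normalized to the vehicle-treated value at the matched timepoint
within each experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import morphology

from .segmentation import remove_small
from .types import LabelMask

__all__ = [
    "InvaginationStats",
    "tophat_enhance",
    "segment_invaginations",
    "invagination_stats",
    "normalize_to_vehicle",
]

DEFAULT_TOPHAT_RADIUS_PX = 7
DEFAULT_MAD_K = 5.0
DEFAULT_MIN_AREA_PX = 4
DEFAULT_PM_EXCLUSION_PX = 3


@dataclass
class InvaginationStats:
    """Per-cell invagination area, normalized to the cell area."""

    label: int
    invag_area_px: int
    cell_area_px: int
    condition: str = ""
    timepoint: float | str = ""
    experiment: str = ""

    @property
    def area_fraction(self) -> float:
        return self.invag_area_px / self.cell_area_px


def tophat_enhance(image: np.ndarray, radius_px: int = DEFAULT_TOPHAT_RADIUS_PX) -> np.ndarray:
    """White top-hat: image minus its opening by a disk of ``radius_px``.

    Output is non-negative and zero on flat regions; bright structures
    narrower than the disk survive at their height above local background.
    """
    image = np.asarray(image, float)
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    if 2 * radius_px + 1 > min(image.shape):
        raise ValueError("structuring element larger than the image")
    return morphology.white_tophat(image, footprint=morphology.disk(radius_px))


def segment_invaginations(
    enhanced: np.ndarray,
    mask: LabelMask,
    threshold_rule: str = "mad",
    mad_k: float = DEFAULT_MAD_K,
    absolute_threshold: float = 0.0,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
    pm_exclusion_px: int = DEFAULT_PM_EXCLUSION_PX,
) -> dict[int, np.ndarray]:
    """Binary invagination mask per cell from a top-hat-enhanced image.

    The search region is the cell interior: the cell mask eroded by
    ``pm_exclusion_px`` so the peripheral membrane ring is not itself
    counted. ``threshold_rule`` is ``"mad"`` (per-cell
    ``median + mad_k * MAD`` of the interior, robust to the bright ring and
    invariant to global intensity rescaling) or ``"absolute"``. Components
    smaller than ``min_area_px`` are removed. An empty result is valid.
    """
    enhanced = np.asarray(enhanced, float)
    if enhanced.shape != mask.data.shape:
        raise ValueError("enhanced image and mask must share one shape")
    if threshold_rule not in ("mad", "absolute"):
        raise ValueError("threshold_rule must be 'mad' or 'absolute'")
    se = morphology.disk(pm_exclusion_px) if pm_exclusion_px > 0 else None

    out: dict[int, np.ndarray] = {}
    for label in mask.labels:
        cell = mask.cell(int(label))
        interior = ndi.binary_erosion(cell, structure=se, border_value=0) if se is not None else cell
        vals = enhanced[interior]
        if vals.size == 0:
            out[int(label)] = np.zeros_like(cell)
            continue
        if threshold_rule == "mad":
            med = np.median(vals)
            mad = np.median(np.abs(vals - med))
            thr = med + mad_k * mad
        else:
            thr = absolute_threshold
        binary = interior & (enhanced > thr)
        binary = remove_small(binary, min_area_px)
        out[int(label)] = binary
    return out


def invagination_stats(
    invag_masks: dict[int, np.ndarray],
    mask: LabelMask,
    condition: str = "",
    timepoint: float | str = "",
    experiment: str = "",
) -> list[InvaginationStats]:
    """Per-cell invagination area sum normalized to the cell area."""
    stats = []
    for label, binary in invag_masks.items():
        cell_area = int((mask.data == label).sum())
        stats.append(
            InvaginationStats(label, int(binary.sum()), cell_area,
                              condition, timepoint, experiment)
        )
    return stats


def normalize_to_vehicle(stats: pd.DataFrame, vehicle_label: str) -> pd.DataFrame:
    """Vehicle-normalize per-condition mean area fractions.

    ``stats`` is a tidy per-cell table with columns ``condition``,
    ``timepoint``, ``experiment`` and ``area_fraction``. For every
    (condition, timepoint, experiment) cell-level fractions are averaged and
    divided by the vehicle average at the same timepoint in the same
    experiment; the vehicle condition therefore normalizes to 1 exactly.
    A missing vehicle raises naming the (timepoint, experiment); a zero
    vehicle mean yields NaN with a flag column.
    """
    required = {"condition", "timepoint", "experiment", "area_fraction"}
    if missing := required - set(stats.columns):
        raise ValueError(f"stats table lacks columns: {sorted(missing)}")
    means = (
        stats.groupby(["condition", "timepoint", "experiment"], sort=False)["area_fraction"]
        .mean()
        .reset_index(name="mean_fraction")
    )
    vehicle = means[means["condition"] == vehicle_label].set_index(["timepoint", "experiment"])[
        "mean_fraction"
    ]

    rows = []
    for _, row in means.iterrows():
        key = (row["timepoint"], row["experiment"])
        if key not in vehicle.index:
            raise ValueError(
                f"no vehicle ({vehicle_label!r}) measurement at timepoint "
                f"{key[0]!r} in experiment {key[1]!r}"
            )
        v = vehicle.loc[key]
        normalized = row["mean_fraction"] / v if v > 0 else float("nan")
        rows.append(
            {
                "condition": row["condition"],
                "timepoint": row["timepoint"],
                "experiment": row["experiment"],
                "mean_fraction": row["mean_fraction"],
                "normalized": normalized,
                "flag": "" if v > 0 else "vehicle-mean-zero",
            }
        )
    return pd.DataFrame(rows)
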