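"""Line-profile analytics: the invagination sorting coefficient and kymographs.

The sorting coefficient compares differential enrichment of a tested
reporter relative to the reference reporter inside a PM invagination versus
an adjacent non-invaginated PM patch of the same cell:

    sorting coefficient = (F_tested / F_reference)|invagination
                          -----------------------------------
                          (F_tested / F_reference)|PM patch

where each F is a background-subtracted fluorescence density integrated
along a line profile. A value of 1 means no differential sorting; the
statistic is invariant under independent positive scaling of either channel.
One invagination is measured per cell.

Profiles are sampled along a polyline by bilinear interpolation and averaged
across a perpendicular band of ``2 * half_width + 1`` lines. A kymograph
stacks the profile of a fixed line over the frames of a timelapse
(time x position).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .types import ImageStack

__all__ = ["LineROI", "SortingMeasurement", "extract_profile", "sorting_coefficient",
           "kymograph"]


@dataclass(frozen=True)
class LineROI:
    """A polyline sampling path: ordered ``(row, col)`` vertices.

    ``step_px`` is the sampling interval along the path; ``half_width_px``
    the number of parallel lines averaged on each side (0 = single line).
    """

    vertices: tuple[tuple[float, float], ...]
    step_px: float = 1.0
    half_width_px: int = 1

    def __post_init__(self) -> None:
        if len(self.vertices) < 2:
            raise ValueError("LineROI needs at least 2 vertices")
        if self.step_px <= 0:
            raise ValueError("step_px must be > 0")
        if self.half_width_px < 0:
            raise ValueError("half_width_px must be >= 0")

    @property
    def length_px(self) -> float:
        v = np.asarray(self.vertices, float)
        return float(np.sum(np.linalg.norm(np.diff(v, axis=0), axis=1)))

    def sample_points(self) -> tuple[np.ndarray, np.ndarray]:
        """Sample coordinates and unit normals along the path."""
        v = np.asarray(self.vertices, float)
        seg = np.diff(v, axis=0)
        seg_len = np.linalg.norm(seg, axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        total = cum[-1]
        if total == 0:
            raise ValueError("degenerate LineROI of zero length")
        distances = np.arange(0.0, total + 1e-9, self.step_px)
        idx = np.clip(np.searchsorted(cum, distances, side="right") - 1, 0, len(seg) - 1)
        frac = (distances - cum[idx]) / np.where(seg_len[idx] > 0, seg_len[idx], 1.0)
        points = v[idx] + seg[idx] * frac[:, None]
        tangents = seg[idx] / np.where(seg_len[idx] > 0, seg_len[idx], 1.0)[:, None]
        normals = np.stack([-tangents[:, 1], tangents[:, 0]], axis=1)
        return points, normals

    @classmethod
    def from_json(cls, path_or_obj) -> "LineROI":
        obj = path_or_obj
        if not isinstance(obj, dict):
            with open(path_or_obj) as fh:
                obj = json.load(fh)
        return cls(
            vertices=tuple(tuple(v) for v in obj["vertices"]),
            step_px=obj.get("step_px", 1.0),
            half_width_px=obj.get("half_width_px", 1),
        )

    def to_json(self) -> dict:
        return {
            "vertices": [list(v) for v in self.vertices],
            "step_px": self.step_px,
            "half_width_px": self.half_width_px,
        }


@dataclass
class SortingMeasurement:
    """Background-subtracted integrated densities and their ratio-of-ratios."""

    label: int
    f_tested_invag: float
    f_ref_invag: float
    f_tested_pm: float
    f_ref_pm: float
    sorting_coefficient: float  # NaN when a denominator density is <= 0
    n_samples: tuple[int, int]  # profile lengths (invagination, pm)
    flags: list[str] = field(default_factory=list)

    @property
    def defined(self) -> bool:
        return np.isfinite(self.sorting_coefficient)


def extract_profile(image: np.ndarray, roi: LineROI) -> np.ndarray:
    """Bilinear line profile averaged across the ROI's perpendicular band.

    Raises if any sample (including band offsets) falls outside the image.
    """
    image = np.asarray(image, float)
    if image.ndim != 2:
        raise ValueError("extract_profile expects a 2-D image")
    points, normals = roi.sample_points()
    offsets = np.arange(-roi.half_width_px, roi.half_width_px + 1)
    coords = points[None, :, :] + offsets[:, None, None] * normals[None, :, :]
    if (
        coords[..., 0].min() < 0
        or coords[..., 1].min() < 0
        or coords[..., 0].max() > image.shape[0] - 1
        or coords[..., 1].max() > image.shape[1] - 1
    ):
        raise ValueError("LineROI (with its band) leaves the image")
    samples = ndi.map_coordinates(
        image, [coords[..., 0].ravel(), coords[..., 1].ravel()], order=1, mode="nearest"
    ).reshape(coords.shape[:2])
    return samples.mean(axis=0)


def _integrated_density(profile: np.ndarray, background: float) -> float:
    """Sum of background-subtracted samples, clamped at zero first.

    Densities are physical, so negative post-subtraction samples are clamped
    to 0 before integration (subtraction strictly precedes integration)."""
    return float(np.clip(np.asarray(profile, float) - background, 0.0, None).sum())


def _background(profile: np.ndarray, rule, channel_index: int) -> float:
    if rule == "min":
        return float(np.min(profile))
    try:
        return float(rule[channel_index])
    except (TypeError, IndexError, KeyError):
        raise ValueError(
            "background_rule must be 'min' or a (tested, reference) value pair"
        ) from None


def sorting_coefficient(
    tested_invag: np.ndarray,
    ref_invag: np.ndarray,
    tested_pm: np.ndarray,
    ref_pm: np.ndarray,
    background_rule="min",
    label: int = 0,
    saturation_value: float | None = None,
) -> SortingMeasurement:
    """Ratio-of-ratios sorting coefficient from four line profiles.

    ``background_rule`` is either a ``(tested, reference)`` pair of mean
    background intensities measured in a cell-free ROI (the default
    analysis), or ``"min"`` to subtract each profile's own minimum.
    Profiles containing ``saturation_value`` are flagged ``saturated``.
    Any non-positive denominator density yields NaN with an ``undefined``
    flag rather than an exception.
    """
    flags: list[str] = []
    if saturation_value is not None and (
        np.max(tested_invag) >= saturation_value or np.max(ref_invag) >= saturation_value
    ):
        flags.append("saturated")

    f_t_inv = _integrated_density(tested_invag, _background(tested_invag, background_rule, 0))
    f_r_inv = _integrated_density(ref_invag, _background(ref_invag, background_rule, 1))
    f_t_pm = _integrated_density(tested_pm, _background(tested_pm, background_rule, 0))
    f_r_pm = _integrated_density(ref_pm, _background(ref_pm, background_rule, 1))

    if f_r_inv <= 0 or f_t_pm <= 0 or f_r_pm <= 0:
        flags.append("undefined")
        coeff = float("nan")
    else:
        coeff = (f_t_inv / f_r_inv) / (f_t_pm / f_r_pm)
    return SortingMeasurement(
        label, f_t_inv, f_r_inv, f_t_pm, f_r_pm, coeff,
        (len(np.atleast_1d(tested_invag)), len(np.atleast_1d(tested_pm))), flags,
    )


def kymograph(timelapse: ImageStack, roi: LineROI, channel: str | int = 0) -> np.ndarray:
    """Intensity along a fixed line over time: shape (n_frames, n_samples).

    The line is assumed fixed across frames (stabilized input); it must stay
    inside the image in every frame.
    """
    if timelapse.axes != "TCYX":
        raise ValueError("kymograph expects a TCYX timelapse")
    rows = [
        extract_profile(timelapse.channel(channel, frame=t), roi)
        for t in range(timelapse.n_frames)
    ]
    return np.stack(rows)
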