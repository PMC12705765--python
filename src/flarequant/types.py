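"""Shared containers for images, label masks and per-cell measurements.

Conventions used throughout the package:

* arrays are ``numpy`` arrays, 0-based, indexed ``(row, col)``;
* multi-channel 2-D images are ``(C, Y, X)``, timelapses ``(T, C, Y, X)``,
  z-stacks ``(Z, Y, X)``;
* label masks are non-negative integers, ``0`` = background;
* physical units: pixel/voxel sizes in micrometres, time in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageStack", "LabelMask", "CellROIs"]


@dataclass
class ImageStack:
    """An intensity array plus the calibration needed to interpret it.

    ``axes`` is one of ``"CYX"`` (multi-channel still), ``"TCYX"``
    (multi-channel timelapse) or ``"ZYX"`` (single-channel z-stack).
    ``pixel_size_um`` applies to Y/X; for z-stacks ``voxel_size_um`` is the
    full ``(z, y, x)`` triple.
    """

    data: np.ndarray
    axes: str
    pixel_size_um: float = 0.1
    frame_interval_min: float | None = None
    channel_names: tuple[str, ...] = ()
    voxel_size_um: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != len(self.axes):
            raise ValueError(
                f"axes {self.axes!r} does not match array of ndim {self.data.ndim}"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0] if "T" in self.axes else 1

    def channel(self, name_or_index: str | int, frame: int | None = None) -> np.ndarray:
        """Return one channel as a 2-D array (for CYX/TCYX stacks)."""
        if isinstance(name_or_index, str):
            try:
                idx = self.channel_names.index(name_or_index)
            except ValueError:
                raise KeyError(f"no channel named {name_or_index!r}") from None
        else:
            idx = int(name_or_index)
        if self.axes == "CYX":
            return self.data[idx]
        if self.axes == "TCYX":
            if frame is None:
                return self.data[:, idx]
            return self.data[frame, idx]
        raise ValueError(f"channel access undefined for axes {self.axes!r}")


@dataclass
class LabelMask:
    """Per-pixel integer cell identities; 0 is background.

    Ids are positive and each id labels one connected cell.
    """

    data: np.ndarray
    pixel_size_um: float = 0.1

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 2:
            raise ValueError("LabelMask must be 2-D")
        if data.min() < 0:
            raise ValueError("labels must be non-negative")
        self.data = data.astype(np.uint16, copy=False) if data.max() < 2**16 else data

    @property
    def labels(self) -> np.ndarray:
        """Sorted array of cell ids present (excluding background)."""
        ids = np.unique(self.data)
        return ids[ids > 0]

    def cell(self, label: int) -> np.ndarray:
        """Boolean mask of one cell."""
        return self.data == label


@dataclass
class CellROIs:
    """Peripheral (PM ring) and internal (cytoplasm) ROIs of one cell.

    The ring marks the plasma membrane: cell mask minus its erosion by
    ``ring_width`` px. The cytoplasm ROI is the erosion by ``erosion_depth``
    px. The two are disjoint whenever ``erosion_depth >= ring_width``.
    """

    label: int
    pm_ring: np.ndarray
    cytoplasm: np.ndarray
    ring_width_px: int
    erosion_depth_px: int
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.pm_ring & self.cytoplasm):
            raise ValueError(f"cell {self.label}: ring and cytoplasm ROIs overlap")
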