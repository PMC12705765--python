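"""3-D lipid-droplet volumetry.

Droplets are segmented as connected components above a threshold in a
z-stack; each object's volume is its voxel count times the voxel volume
(anisotropic voxels allowed). Objects are assigned to cells by majority
overlap with a per-cell mask — either a 2-D mask extruded along z or a full
3-D label volume. Connectivity defaults to 26 and the threshold to Otsu on
the whole stack; both are the main sources of sensitivity for absolute
volumes and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import filters, measure

from .types import LabelMask

__all__ = ["DropletStats", "count_objects_3d"]

_CONNECTIVITY = {6: 1, 18: 2, 26: 3}  # neighbor count -> skimage rank


@dataclass
class DropletStats:
    """Per-cell droplet census: count, per-object volumes, and their total."""

    label: int  # 0 = unassigned / whole field
    n_droplets: int
    volumes_um3: list[float] = field(default_factory=list)
    threshold: float = float("nan")

    @property
    def total_volume_um3(self) -> float:
        return float(sum(self.volumes_um3))


def count_objects_3d(
    stack: np.ndarray,
    voxel_size_um: tuple[float, float, float],
    threshold: float | str = "otsu",
    connectivity: int = 26,
    min_voxels: int = 2,
    cell_mask: LabelMask | np.ndarray | None = None,
) -> list[DropletStats]:
    """Count above-threshold connected components and measure their volumes.

    ``threshold`` is an absolute intensity or ``"otsu"``; a threshold above
    the stack maximum yields zero objects (valid, not an error).
    ``connectivity`` is 6, 18 or 26 (voxel neighborhoods). Objects below
    ``min_voxels`` voxels are discarded (suppresses single-voxel shot noise;
    set to 1 to keep everything). ``cell_mask``
    assigns objects to cells by majority overlap: a 2-D :class:`LabelMask`
    is extruded along z, a 3-D integer array is used as-is; without a mask a
    single field-level record (label 0) is returned.
    """
    stack = np.asarray(stack, float)
    if stack.ndim != 3:
        raise ValueError("count_objects_3d expects a 3-D stack (ZYX)")
    if connectivity not in _CONNECTIVITY:
        raise ValueError("connectivity must be 6, 18 or 26")
    thr = float(filters.threshold_otsu(stack)) if threshold == "otsu" else float(threshold)

    binary = stack > thr
    voxel_volume = float(np.prod(voxel_size_um))
    labels = measure.label(binary, connectivity=_CONNECTIVITY[connectivity])

    if cell_mask is None:
        cells3d = None
    elif isinstance(cell_mask, LabelMask):
        cells3d = np.broadcast_to(cell_mask.data, stack.shape)
    else:
        cell_mask = np.asarray(cell_mask)
        cells3d = (
            np.broadcast_to(cell_mask, stack.shape) if cell_mask.ndim == 2 else cell_mask
        )
        if cells3d.shape != stack.shape:
            raise ValueError("cell mask shape incompatible with stack")

    per_cell: dict[int, list[float]] = {}
    for obj in range(1, int(labels.max()) + 1):
        sel = labels == obj
        n_vox = int(sel.sum())
        if n_vox < min_voxels:
            continue
        volume = n_vox * voxel_volume
        if cells3d is None:
            cell = 0
        else:
            ids, counts = np.unique(cells3d[sel], return_counts=True)
            cell = int(ids[np.argmax(counts)])
        per_cell.setdefault(cell, []).append(volume)

    if cells3d is None:
        vols = per_cell.get(0, [])
        return [DropletStats(0, len(vols), vols, thr)]
    all_ids = sorted(set(np.unique(cells3d[cells3d > 0]).tolist()) | set(per_cell) - {0})
    return [
        DropletStats(int(cid), len(per_cell.get(cid, [])), per_cell.get(cid, []), thr)
        for cid in all_ids
    ]
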