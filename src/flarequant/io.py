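"""Readers and writers: multi-page TIFF, tidy CSV, JSON (ROIs, ground truth,
provenance). Every writer round-trips bit-exactly through its reader.

TIFF axis orders are explicit: stills ``CYX``, timelapses ``TCYX``, z-stacks
``ZYX``; calibration travels in the TIFF description as JSON.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .types import ImageStack, LabelMask

__all__ = [
    "write_image",
    "read_image",
    "write_labels",
    "read_labels",
    "write_cells_csv",
    "read_cells_csv",
    "write_json",
    "read_json",
    "write_provenance",
]

CELL_CSV_SCHEMA = "flarequant.cells/1"


def write_image(path, stack: ImageStack) -> Path:
    """Write an :class:`ImageStack` as multi-page TIFF with JSON metadata."""
    path = Path(path)
    meta = {
        "axes": stack.axes,
        "pixel_size_um": stack.pixel_size_um,
        "frame_interval_min": stack.frame_interval_min,
        "channel_names": list(stack.channel_names),
        "voxel_size_um": list(stack.voxel_size_um) if stack.voxel_size_um else None,
    }
    tifffile.imwrite(path, stack.data, description=json.dumps(meta))
    return path


def read_image(path) -> ImageStack:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    meta = json.loads(desc)
    return ImageStack(
        data,
        axes=meta["axes"],
        pixel_size_um=meta["pixel_size_um"],
        frame_interval_min=meta.get("frame_interval_min"),
        channel_names=tuple(meta.get("channel_names") or ()),
        voxel_size_um=tuple(meta["voxel_size_um"]) if meta.get("voxel_size_um") else None,
    )


def write_labels(path, mask: LabelMask) -> Path:
    path = Path(path)
    tifffile.imwrite(
        path,
        mask.data.astype(np.uint16),
        description=json.dumps({"pixel_size_um": mask.pixel_size_um}),
    )
    return path


def read_labels(path) -> LabelMask:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    pixel_size = 0.1
    try:
        pixel_size = json.loads(desc).get("pixel_size_um", 0.1)
    except (json.JSONDecodeError, TypeError):
        pass  # external masks may carry no metadata
    return LabelMask(data, pixel_size)


def _as_row(obj) -> dict:
    d = dataclasses.asdict(obj)
    if "flags" in d:
        d["flags"] = ";".join(d["flags"])
    for k, v in list(d.items()):
        if isinstance(v, (tuple, list, dict)):
            d[k] = json.dumps(v)
    return d


def write_cells_csv(path, records, extra_columns: dict | None = None) -> Path:
    """Write per-cell measurement dataclasses (or a DataFrame) as tidy CSV."""
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([_as_row(r) for r in records])
    for k, v in (extra_columns or {}).items():
        df[k] = v
    df.insert(0, "schema", CELL_CSV_SCHEMA)
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def read_cells_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "schema" in df.columns:
        df = df.drop(columns=["schema"])
    return df


def write_json(path, obj) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))
    return path


def read_json(path):
    return json.loads(Path(path).read_text())


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_provenance(path, config: dict, seed: int, extra: dict | None = None) -> Path:
    """Record everything needed to reproduce a run: config, seed, versions."""
    payload = {
        "schema": "flarequant.provenance/1",
        "flarequant_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": seed,
        "config": config,
    }
    if extra:
        payload.update(extra)
    return write_json(path, payload)
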