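"""End-to-end driver: simulate -> segment -> quantify -> summarize.

Runs two experimental arms from one validated config — a treated arm with
the configured internalization kinetics and a vehicle arm with static
kinetics — then measures per-cell colocalization, PM enrichment,
invagination area fractions (vehicle-normalized) and sorting coefficients at
a pre-treatment and a post-treatment frame, extracts a kymograph across one
invagination, and writes a tidy per-cell CSV, a summary CSV, kymograph TIFFs
and a provenance JSON that suffices to reproduce the run exactly.
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import io as fio
from .coloc import pcc_per_cell
from .enrichment import median_background_subtract, pm_enrichment
from .invagination import (
    invagination_stats,
    normalize_to_vehicle,
    segment_invaginations,
    tophat_enhance,
)
from .segmentation import exclude_border_cells, make_rois, segment_cells
from .sorting_kymo import LineROI, extract_profile, kymograph, sorting_coefficient
from .synthgen import (
    KineticsSpec,
    NoiseSpec,
    generate_timelapse,
    random_cell_specs,
    truth_profile_lines,
)
from .types import ImageStack, LabelMask

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


class CellsConfig(BaseModel):
    n_cells: int = Field(6, ge=1)
    border_cells: int = Field(1, ge=0)
    pm_fraction: float = Field(0.6, ge=0.0, le=1.0)
    sorting_factor: float = Field(2.0, ge=0.0)
    n_invaginations: int = Field(2, ge=0)
    vehicle_n_invaginations: int = Field(1, ge=0)
    n_foci: int = Field(2, ge=0)
    base_intensity: float = Field(200.0, gt=0)
    foci_intensity: float = Field(300.0, ge=0)


class KineticsConfig(BaseModel):
    t_treat_min: float = Field(3.0, gt=0)
    spike_amplitude: float = Field(0.0, ge=0)
    spike_decay_per_min: float = Field(1.0, ge=0)
    internalization_rate_per_min: float = Field(0.3, ge=0)
    pm_fraction_end: float = Field(0.2, ge=0, le=1)
    foci_growth_rate_per_min: float = Field(0.2, ge=0)

    def to_spec(self, k_override: float | None = None) -> KineticsSpec:
        k = self.internalization_rate_per_min if k_override is None else k_override
        return KineticsSpec(
            t_treat_min=self.t_treat_min,
            spike_amplitude=self.spike_amplitude,
            spike_decay_per_min=self.spike_decay_per_min,
            internalization_rate_per_min=k,
            pm_fraction_end=self.pm_fraction_end,
            foci_growth_rate_per_min=self.foci_growth_rate_per_min,
        )


class NoiseConfig(BaseModel):
    gain: float = Field(2.0, gt=0)
    read_sigma: float = Field(2.0, ge=0)
    background_level: float = Field(100.0, ge=0)
    background_gradient: float = 0.0
    shot_noise: bool = True


class PipelineConfig(BaseModel):
    """Validated configuration of one end-to-end run."""

    seed: int = 0
    shape: tuple[int, int] = (256, 256)
    n_frames: int = Field(10, ge=2)
    frame_interval_min: float = Field(1.0, gt=0)
    pre_offset_min: float = Field(1.0, gt=0)
    post_offset_min: float = Field(5.0, gt=0)
    cells: CellsConfig = CellsConfig()
    kinetics: KineticsConfig = KineticsConfig()
    noise: NoiseConfig = NoiseConfig()
    segmentation: str = Field("truth", pattern="^(truth|builtin)$")
    ring_width_px: int = Field(3, ge=1)
    erosion_depth_px: int = Field(6, ge=1)
    background_kernel_px: int = Field(101, ge=3)
    tophat_radius_px: int = Field(7, ge=1)
    mad_k: float = Field(5.0, gt=0)
    min_area_px: int = Field(4, ge=1)
    condition: str = "treated"
    vehicle: str = "vehicle"
    experiment: str = "exp1"

    @model_validator(mode="after")
    def _check_frames(self) -> "PipelineConfig":
        t_max = (self.n_frames - 1) * self.frame_interval_min
        if self.kinetics.t_treat_min - self.pre_offset_min < 0:
            raise ValueError("pre-treatment frame falls before frame 0")
        if self.kinetics.t_treat_min + self.post_offset_min > t_max:
            raise ValueError("post-treatment frame falls after the last frame")
        if self.erosion_depth_px < self.ring_width_px:
            raise ValueError("erosion_depth_px must be >= ring_width_px")
        return self


def _frame_index(cfg: PipelineConfig, offset: float) -> int:
    return int(round((cfg.kinetics.t_treat_min + offset) / cfg.frame_interval_min))


def _background_pair(stack: ImageStack, labels: LabelMask, frame: int) -> tuple[float, float]:
    """Median cell-free intensity per channel (tested, reference)."""
    bg = labels.data == 0
    tested = float(np.median(stack.channel("tested", frame)[bg]))
    ref = float(np.median(stack.channel("reference", frame)[bg]))
    return tested, ref


def _run_arm(cfg: PipelineConfig, condition: str, k: float, n_invag: int, seed: int):
    """Simulate and quantify one arm; return tidy rows plus artifacts."""
    specs = random_cell_specs(
        cfg.cells.n_cells,
        shape=cfg.shape,
        seed=seed,
        border_cells=cfg.cells.border_cells,
        pm_fraction=cfg.cells.pm_fraction,
        sorting_factor=cfg.cells.sorting_factor,
        n_invaginations=n_invag,
        n_foci=cfg.cells.n_foci,
        base_intensity=cfg.cells.base_intensity,
        foci_intensity=cfg.cells.foci_intensity,
    )
    noise = NoiseSpec(seed=seed + 1, **cfg.noise.model_dump())
    stack, truth_mask, gt = generate_timelapse(
        specs, cfg.kinetics.to_spec(k_override=k), noise,
        n_frames=cfg.n_frames, frame_interval_min=cfg.frame_interval_min, shape=cfg.shape,
    )

    pre, post = _frame_index(cfg, -cfg.pre_offset_min), _frame_index(cfg, cfg.post_offset_min)
    if cfg.segmentation == "truth":
        mask = truth_mask
    else:
        mask = segment_cells(stack.channel("reference", pre),
                             pixel_size_um=stack.pixel_size_um)
    mask = exclude_border_cells(mask)
    rois = make_rois(mask, cfg.ring_width_px, cfg.erosion_depth_px)
    drops = Counter()
    drops["border"] = len(specs) - mask.labels.size
    drops["degenerate-roi"] = mask.labels.size - len(rois)

    rows: list[dict] = []

    def emit(measure, label, timepoint, value, flags=""):
        rows.append(
            {
                "measure": measure,
                "label": int(label),
                "condition": condition,
                "timepoint": timepoint,
                "experiment": cfg.experiment,
                "value": value,
                "flags": flags,
            }
        )

    for name, frame in (("pre", pre), ("post", post)):
        tested = stack.channel("tested", frame)
        ref = stack.channel("reference", frame)

        for r in pcc_per_cell(tested, ref, mask, condition=condition,
                              timepoint=name, experiment=cfg.experiment):
            emit("pcc", r.label, name, r.pcc, ";".join(r.flags))
            if not r.defined:
                drops["undefined-pcc"] += 1

        subtracted = median_background_subtract(tested, cfg.background_kernel_px)
        for e in pm_enrichment(subtracted, rois, timepoint=name,
                               condition=condition, experiment=cfg.experiment):
            emit("pm_enrichment", e.label, name, e.ratio, ";".join(e.flags))

        enhanced = tophat_enhance(ref, cfg.tophat_radius_px)
        invag_masks = segment_invaginations(
            enhanced, mask, mad_k=cfg.mad_k, min_area_px=cfg.min_area_px,
            pm_exclusion_px=cfg.ring_width_px,
        )
        for s in invagination_stats(invag_masks, mask, condition=condition,
                                    timepoint=name, experiment=cfg.experiment):
            emit("invagination_area_fraction", s.label, name, s.area_fraction)

    # sorting coefficient: one invagination per cell, measured pre-treatment
    bg_pair = _background_pair(stack, truth_mask, pre)
    tested_pre = stack.channel("tested", pre)
    ref_pre = stack.channel("reference", pre)
    kymo_roi = None
    for label in mask.labels:
        label = int(label)
        if not gt.invagination_axes.get(label):
            continue
        lines = truth_profile_lines(gt, label)
        roi_inv = LineROI(tuple(lines["invagination"]), step_px=0.5, half_width_px=0)
        roi_pm = LineROI(tuple(lines["pm"]), step_px=0.5, half_width_px=0)
        m = sorting_coefficient(
            extract_profile(tested_pre, roi_inv), extract_profile(ref_pre, roi_inv),
            extract_profile(tested_pre, roi_pm), extract_profile(ref_pre, roi_pm),
            background_rule=bg_pair, label=label,
        )
        emit("sorting_coefficient", label, "pre", m.sorting_coefficient, ";".join(m.flags))
        if kymo_roi is None:
            kymo_roi = _kymo_line(gt, label)

    kymo = kymograph(stack, kymo_roi, channel="tested") if kymo_roi is not None else None
    logger.info("arm %s: drops %s", condition, dict(drops))
    return rows, stack, truth_mask, gt, kymo, dict(drops)


def _kymo_line(gt, label: int) -> LineROI:
    """Radial line through the first invagination: outside -> cytoplasm."""
    spec = gt.cell_specs[gt.labels.index(label)]
    (p0, p1) = gt.invagination_axes[label][0]
    p0, p1 = np.array(p0), np.array(p1)
    u = (p1 - p0) / np.linalg.norm(p1 - p0)
    start = p0 - u * (spec.pm_ring_width + 4)  # just outside the cell
    end = p1 + u * 2
    return LineROI((tuple(start), tuple(end)), step_px=0.5, half_width_px=1)


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run both arms, write all outputs, return the result bundle.

    Outputs under ``out_dir``: ``cells.csv`` (tidy, one row per cell and
    measure), ``summary.csv``, ``invagination_normalized.csv``,
    ``kymograph_<arm>.tif``, ``labels_<arm>.tif``, ``groundtruth_<arm>.json``
    and ``provenance.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    arms = [
        (config.condition, config.kinetics.internalization_rate_per_min,
         config.cells.n_invaginations, config.seed),
        (config.vehicle, 0.0, config.cells.vehicle_n_invaginations, config.seed + 1000),
    ]
    all_rows: list[dict] = []
    drops: dict[str, dict] = {}
    for condition, k, n_invag, seed in arms:
        rows, stack, truth_mask, gt, kymo, arm_drops = _run_arm(
            config, condition, k, n_invag, seed
        )
        all_rows.extend(rows)
        drops[condition] = arm_drops
        fio.write_labels(out / f"labels_{condition}.tif", truth_mask)
        fio.write_json(out / f"groundtruth_{condition}.json", gt.to_dict())
        if kymo is not None:
            fio.write_image(
                out / f"kymograph_{condition}.tif",
                ImageStack(kymo.astype(np.float32), "YX",  # rows = time, cols = position
                           pixel_size_um=stack.pixel_size_um,
                           frame_interval_min=stack.frame_interval_min),
            )

    cells = pd.DataFrame(all_rows)
    fio.write_cells_csv(out / "cells.csv", cells)

    defined = cells.dropna(subset=["value"])
    summary = (
        defined.groupby(["measure", "condition", "timepoint"], sort=False)["value"]
        .agg(
            median="median",
            q1=lambda v: float(np.percentile(v, 25)),
            q3=lambda v: float(np.percentile(v, 75)),
            n_cells="count",
        )
        .reset_index()
    )
    summary.to_csv(out / "summary.csv", index=False, float_format="%.10g")

    invag = cells[cells["measure"] == "invagination_area_fraction"].rename(
        columns={"value": "area_fraction"}
    )
    normalized = normalize_to_vehicle(invag, vehicle_label=config.vehicle)
    normalized.to_csv(out / "invagination_normalized.csv", index=False, float_format="%.10g")

    fio.write_provenance(out / "provenance.json", config.model_dump(), config.seed,
                         extra={"cell_drop_reasons": drops})
    return {
        "cells": cells,
        "summary": summary,
        "invagination_normalized": normalized,
        "out_dir": out,
        "drop_reasons": drops,
    }
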