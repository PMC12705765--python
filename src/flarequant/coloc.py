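"""Per-cell Pearson colocalization and the hierarchical test procedure.

The colocalization score is the plain Pearson correlation coefficient (PCC)
of the two channels' intensities over all pixels of each cell mask — no
intensity thresholding (Costes/Otsu pre-masking is deliberately not applied;
whole-cell-mask PCC is the documented choice). Group comparisons are made on
per-experiment mean PCCs, not pooled cells: normality of the experiment
means is checked with Shapiro-Wilk, then an unpaired two-sample t test is
applied (Student pooled-variance by default, Welch by flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import LabelMask

__all__ = ["ColocResult", "GroupComparison", "pcc_per_cell", "compare_conditions",
           "summarize_cells"]

MIN_PIXELS_DEFAULT = 50


@dataclass
class ColocResult:
    """Single-cell colocalization score."""

    label: int
    pcc: float  # NaN when undefined (zero variance in either channel)
    n_pixels: int
    condition: str = ""
    timepoint: float | str = ""
    experiment: str = ""
    flags: list[str] = field(default_factory=list)

    @property
    def defined(self) -> bool:
        return np.isfinite(self.pcc)


@dataclass
class GroupComparison:
    """Unpaired t test on per-experiment mean PCCs of two conditions."""

    means_a: list[float]
    means_b: list[float]
    shapiro_p_a: float
    shapiro_p_b: float
    t_statistic: float
    p_value: float
    n_experiments: tuple[int, int]
    equal_var: bool
    normality_questionable: bool


def pcc_per_cell(
    channel_a: np.ndarray,
    channel_b: np.ndarray,
    mask: LabelMask,
    min_pixels: int = MIN_PIXELS_DEFAULT,
    condition: str = "",
    timepoint: float | str = "",
    experiment: str = "",
) -> list[ColocResult]:
    """Pearson correlation of two co-registered channels over each cell mask.

    Cells with zero variance in either channel get ``pcc = NaN`` with an
    ``undefined-pcc`` flag (excluded from summaries rather than set to 0,
    which would bias medians); cells below ``min_pixels`` are flagged
    ``too-few-pixels``.
    """
    a = np.asarray(channel_a, float)
    b = np.asarray(channel_b, float)
    if a.shape != b.shape or a.shape != mask.data.shape:
        raise ValueError("channels and mask must share one shape")
    labels = mask.labels
    if labels.size == 0:
        raise ValueError("empty label mask")

    results = []
    for label in labels:
        sel = mask.data == label
        xa, xb = a[sel], b[sel]
        flags = []
        if xa.size < min_pixels:
            flags.append("too-few-pixels")
        if xa.size < 2 or np.ptp(xa) == 0 or np.ptp(xb) == 0:
            flags.append("undefined-pcc")
            pcc = float("nan")
        else:
            pcc = float(stats.pearsonr(xa, xb).statistic)
        results.append(ColocResult(int(label), pcc, int(xa.size),
                                   condition, timepoint, experiment, flags))
    return results


def _experiment_means(results: list[ColocResult]) -> pd.Series:
    rows = [(r.experiment, r.pcc) for r in results if r.defined]
    if not rows:
        raise ValueError("no defined PCC values")
    df = pd.DataFrame(rows, columns=["experiment", "pcc"])
    return df.groupby("experiment")["pcc"].mean()


def compare_conditions(
    results_a: list[ColocResult],
    results_b: list[ColocResult],
    equal_var: bool = True,
    alpha_normality: float = 0.05,
) -> GroupComparison:
    """Two-condition comparison on per-experiment mean PCCs.

    Requires at least three experiments per group (Shapiro-Wilk needs
    n >= 3). If either group's normality p falls below
    ``alpha_normality`` the comparison is flagged questionable — reported,
    never auto-switched to a different test.
    """
    means_a = _experiment_means(results_a)
    means_b = _experiment_means(results_b)
    if len(means_a) < 3 or len(means_b) < 3:
        raise ValueError(
            f"need >= 3 experiments per group for the normality check, "
            f"got {len(means_a)} and {len(means_b)}"
        )
    sw_a = float(stats.shapiro(means_a).pvalue)
    sw_b = float(stats.shapiro(means_b).pvalue)
    tt = stats.ttest_ind(means_a, means_b, equal_var=equal_var)
    return GroupComparison(
        means_a=list(means_a),
        means_b=list(means_b),
        shapiro_p_a=sw_a,
        shapiro_p_b=sw_b,
        t_statistic=float(tt.statistic),
        p_value=float(tt.pvalue),
        n_experiments=(len(means_a), len(means_b)),
        equal_var=equal_var,
        normality_questionable=(sw_a < alpha_normality or sw_b < alpha_normality),
    )


def summarize_cells(results: list[ColocResult]) -> pd.DataFrame:
    """Superplot-style summary per condition/timepoint.

    Median and interquartile range (linear-interpolation quantiles) over
    cells, cell count, and per-experiment means as a nested table column.
    Undefined cells are excluded and counted.
    """
    if not results:
        raise ValueError("no results to summarize")
    df = pd.DataFrame(
        {
            "condition": [r.condition for r in results],
            "timepoint": [r.timepoint for r in results],
            "experiment": [r.experiment for r in results],
            "pcc": [r.pcc for r in results],
        }
    )
    n_undefined = int(df["pcc"].isna().sum())
    defined = df.dropna(subset=["pcc"])

    def _agg(group: pd.DataFrame) -> pd.Series:
        q1, med, q3 = np.percentile(group["pcc"], [25, 50, 75])  # linear (type-7)
        exp_means = group.groupby("experiment")["pcc"].mean()
        return pd.Series(
            {
                "median": med,
                "q1": q1,
                "q3": q3,
                "n_cells": len(group),
                "n_experiments": exp_means.size,
                "experiment_means": dict(exp_means),
            }
        )

    out = (
        defined.groupby(["condition", "timepoint"], sort=False)[defined.columns]
        .apply(_agg)
        .reset_index()
    )
    out.attrs["n_undefined_cells"] = n_undefined
    return out
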