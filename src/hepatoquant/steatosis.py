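"""Percentage steatosis and lipid-droplet morphometry from segmentation maps.

Percentage steatosis is defined as the SRS signal of lipid over the combined
SRS signals of lipid, protein, and DNA (x100), i.e. an intensity-weighted
share; unassigned signal is excluded from the denominator.  Droplets are
8-connected components of the lipid mask; each is summarized by its
equivalent circular diameter (d = 2 sqrt(area/pi) x pixel size) and flagged
microvesicular (< 1 um) or macrovesicular (>= 1 um).  Samples aggregate
frame-level results, and groups are compared with a paired two-tailed
Student's t-test (significance at p <= 0.05), with an unpaired Welch option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .phasor import SegmentationMap

__all__ = [
    "CompositionSummary",
    "SampleSummary",
    "GroupComparison",
    "percentage_steatosis",
    "detect_droplets",
    "summarize_sample",
    "compare_groups",
]

MICRO_MACRO_CUTOFF_UM = 1.0


@dataclass(frozen=True)
class CompositionSummary:
    """Summed per-class SRS signals of one frame and the derived steatosis %."""

    lipid_signal: float
    protein_signal: float
    dna_signal: float
    percent_steatosis: float


@dataclass(frozen=True)
class SampleSummary:
    """Per-sample aggregate over frames."""

    sample_id: str
    n_frames: int
    mean_percent_steatosis: float
    sd_percent_steatosis: float
    droplet_count: int
    mean_droplet_diameter_um: float


@dataclass(frozen=True)
class MetricComparison:
    normal_mean: float
    nash_mean: float
    ratio_nash_over_normal: float
    t_statistic: float
    p_value: float  # NaN when the paired differences have zero variance
    significant: bool
    degenerate_variance: bool


@dataclass(frozen=True)
class GroupComparison:
    """NASH-vs-normal comparison of steatosis and droplet morphometry."""

    percent_steatosis: MetricComparison
    droplet_diameter: MetricComparison
    droplet_count: MetricComparison
    test: str  # "paired" or "welch"


def percentage_steatosis(
    seg: SegmentationMap, weighting: Literal["intensity", "pixel"] = "intensity"
) -> CompositionSummary:
    """Compute percentage steatosis from a segmentation map.

    ``weighting="intensity"`` (default) uses summed SRS signal per class;
    ``"pixel"`` uses pixel counts instead.

    Raises
    ------
    ValueError
        If all three class signals are zero (no tissue in frame).
    """
    if weighting == "intensity":
        lipid = seg.class_signal.get("lipid", 0.0)
        protein = seg.class_signal.get("protein", 0.0)
        dna = seg.class_signal.get("dna", 0.0)
    elif weighting == "pixel":
        lipid = float(seg.mask("lipid").sum())
        protein = float(seg.mask("protein").sum())
        dna = float(seg.mask("dna").sum())
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    denom = lipid + protein + dna
    if denom <= 0:
        raise ValueError("all class signals are zero: empty tissue frame")
    return CompositionSummary(
        lipid_signal=lipid,
        protein_signal=protein,
        dna_signal=dna,
        percent_steatosis=100.0 * lipid / denom,
    )


def detect_droplets(
    seg: SegmentationMap, pixel_size: float, min_area_px: int = 1
) -> pd.DataFrame:
    """Detect lipid droplets as 8-connected components of the lipid mask.

    Returns a table with one row per droplet: ``centroid_row``,
    ``centroid_col`` (px), ``area_px``, ``equivalent_diameter_um`` and
    ``droplet_class`` (micro if < 1 um, else macro).  Droplets touching the
    frame border are kept.  An empty lipid mask yields an empty table.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    mask = seg.mask("lipid")
    labeled = cc_label(mask, connectivity=2)
    rows = []
    for region in regionprops(labeled):
        if region.area < min_area_px:
            continue
        d_um = pixel_size * 2.0 * np.sqrt(region.area / np.pi)
        rows.append(
            {
                "centroid_row": region.centroid[0],
                "centroid_col": region.centroid[1],
                "area_px": int(region.area),
                "equivalent_diameter_um": d_um,
                "droplet_class": "micro" if d_um < MICRO_MACRO_CUTOFF_UM else "macro",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "centroid_row",
            "centroid_col",
            "area_px",
            "equivalent_diameter_um",
            "droplet_class",
        ],
    )


def summarize_sample(
    frames: Sequence[tuple[CompositionSummary, pd.DataFrame]], sample_id: str
) -> SampleSummary:
    """Aggregate frame-level composition and droplet tables for one sample.

    Mean/SD of percent steatosis across frames (sample SD, ddof=1; 0 for a
    single frame); droplet statistics pooled over all frames.
    """
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    pcts = np.array([c.percent_steatosis for c, _ in frames])
    tables = [t for _, t in frames if len(t)]
    diam = (
        np.concatenate([t["equivalent_diameter_um"].to_numpy() for t in tables])
        if tables
        else np.array([])
    )
    return SampleSummary(
        sample_id=sample_id,
        n_frames=len(frames),
        mean_percent_steatosis=float(pcts.mean()),
        sd_percent_steatosis=float(pcts.std(ddof=1)) if len(pcts) > 1 else 0.0,
        droplet_count=int(diam.size),
        mean_droplet_diameter_um=float(diam.mean()) if diam.size else np.nan,
    )


def _compare_metric(
    normal: np.ndarray, nash: np.ndarray, test: str
) -> MetricComparison:
    normal_mean = float(np.mean(normal))
    nash_mean = float(np.mean(nash))
    ratio = nash_mean / normal_mean if normal_mean != 0 else np.nan
    degenerate = False
    if test == "paired":
        diffs = nash - normal
        if np.allclose(diffs.std(ddof=0), 0.0):
            degenerate = True
            t_stat, p = np.nan, np.nan
        else:
            t_stat, p = stats.ttest_rel(nash, normal)
    else:  # welch
        if np.allclose(np.std(normal), 0) and np.allclose(np.std(nash), 0):
            degenerate = True
            t_stat, p = np.nan, np.nan
        else:
            t_stat, p = stats.ttest_ind(nash, normal, equal_var=False)
    return MetricComparison(
        normal_mean=normal_mean,
        nash_mean=nash_mean,
        ratio_nash_over_normal=float(ratio),
        t_statistic=float(t_stat),
        p_value=float(p),
        significant=bool(np.isfinite(p) and p <= 0.05),
        degenerate_variance=degenerate,
    )


def compare_groups(
    normal: Sequence[SampleSummary],
    nash: Sequence[SampleSummary],
    test: Literal["paired", "welch"] = "paired",
) -> GroupComparison:
    """Compare NASH vs normal sample summaries metric by metric.

    The default paired two-tailed t-test pairs samples by list index (the
    cohort's paired design); ``test="welch"`` gives an unpaired alternative.

    Raises
    ------
    ValueError
        If group sizes differ under the paired design.
    """
    if test == "paired" and len(normal) != len(nash):
        raise ValueError(
            f"paired comparison pairs samples by index and needs equal group sizes "
            f"(got {len(normal)} normal vs {len(nash)} NASH); use test='welch' otherwise"
        )
    if not normal or not nash:
        raise ValueError("both groups must be non-empty")

    def col(summaries: Sequence[SampleSummary], attr: str) -> np.ndarray:
        return np.array([getattr(s, attr) for s in summaries], dtype=float)

    return GroupComparison(
        percent_steatosis=_compare_metric(
            col(normal, "mean_percent_steatosis"), col(nash, "mean_percent_steatosis"), test
        ),
        droplet_diameter=_compare_metric(
            col(normal, "mean_droplet_diameter_um"), col(nash, "mean_droplet_diameter_um"), test
        ),
        droplet_count=_compare_metric(
            col(normal, "droplet_count"), col(nash, "droplet_count"), test
        ),
        test=test,
    )
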