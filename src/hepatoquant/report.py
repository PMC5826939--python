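"""Cohort-level assembly: isoform heat maps, differential tables, full report.

Combines per-sample imaging (percentage steatosis, droplet morphometry) and
proteomic (isoform relative concentration) results into the cohort outputs:
a protein x isoform by sample concentration table, a NASH-vs-normal
differential table with paired two-tailed t-tests (p <= 0.05 significance),
dual heat maps (relative concentrations on a 0-1 scale; NASH/normal ratio on
a symmetric log2 scale), and a combined JSON report.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cief import PTM_ORDER, IsoformProfile, quantify_trace
from .phasor import default_gates, phasor_transform, segment_by_gates
from .steatosis import (
    GroupComparison,
    compare_groups,
    detect_droplets,
    percentage_steatosis,
    summarize_sample,
)
from .synthetic import Electropherogram, HyperspectralStack, make_reference_spectra

__all__ = [
    "build_cohort_table",
    "differential_analysis",
    "render_heatmaps",
    "full_report",
]


def build_cohort_table(
    profiles: Mapping[str, Mapping[str, IsoformProfile]],
    manifest: Mapping,
) -> pd.DataFrame:
    """Assemble per-sample isoform profiles into a cohort table.

    ``profiles[sample_id][protein]`` holds the quantified profile.  Rows are
    a (protein, isoform) MultiIndex with proteins alphabetical and isoforms
    in canonical order (unmodified, phospho, acetyl, glycosyl — zeros where
    absent, so per-protein column blocks sum to 1); columns follow manifest
    sample order.  Group labels are stored in ``df.attrs["groups"]``.

    Raises
    ------
    KeyError
        If any sample lacks a profile for any protein.
    """
    sample_ids = [s["sample_id"] for s in manifest["samples"]]
    groups = {s["sample_id"]: s["group"] for s in manifest["samples"]}
    proteins = sorted(manifest["proteins"])
    for sid in sample_ids:
        if sid not in profiles:
            raise KeyError(f"missing profiles for sample {sid!r}")
        for prot in proteins:
            if prot not in profiles[sid]:
                raise KeyError(f"missing protein {prot!r} for sample {sid!r}")
    index = pd.MultiIndex.from_product(
        [proteins, list(PTM_ORDER)], names=["protein", "isoform"]
    )
    table = pd.DataFrame(0.0, index=index, columns=sample_ids)
    for sid in sample_ids:
        for prot in proteins:
            for iso, v in profiles[sid][prot].relative_concentration.items():
                table.loc[(prot, iso), sid] = v
    table.attrs["groups"] = [groups[sid] for sid in sample_ids]
    return table


def differential_analysis(
    table: pd.DataFrame,
    test: str = "paired",
    fdr_correction: bool = False,
) -> pd.DataFrame:
    """NASH-vs-normal statistics per protein x isoform row.

    Pairs samples by within-group index order.  Reports group means/SDs, the
    nash/normal mean ratio (NaN-flagged when the normal mean is zero), the
    paired two-tailed t p-value (NaN when the paired differences have zero
    variance), and a significance flag at p <= 0.05.  ``fdr_correction``
    applies Benjamini-Hochberg across rows (off by default).
    """
    groups = np.array(table.attrs["groups"])
    normal_cols = table.columns[groups == "normal"]
    nash_cols = table.columns[groups == "nash"]
    if len(normal_cols) == 0 or len(nash_cols) == 0:
        raise ValueError("both groups must be non-empty")
    if test == "paired" and len(normal_cols) != len(nash_cols):
        raise ValueError("paired analysis pairs by index and needs equal group sizes")
    rows = []
    for key, row in table.iterrows():
        normal = row[normal_cols].to_numpy(dtype=float)
        nash = row[nash_cols].to_numpy(dtype=float)
        ratio = nash.mean() / normal.mean() if normal.mean() != 0 else np.nan
        if test == "paired":
            diffs = nash - normal
            if np.allclose(diffs.std(ddof=0), 0):
                t_stat, p = np.nan, np.nan
            else:
                t_stat, p = stats.ttest_rel(nash, normal)
        else:
            if np.allclose(normal.std(), 0) and np.allclose(nash.std(), 0):
                t_stat, p = np.nan, np.nan
            else:
                t_stat, p = stats.ttest_ind(nash, normal, equal_var=False)
        rows.append(
            {
                "protein": key[0],
                "isoform": key[1],
                "normal_mean": normal.mean(),
                "normal_sd": normal.std(ddof=1) if len(normal) > 1 else 0.0,
                "nash_mean": nash.mean(),
                "nash_sd": nash.std(ddof=1) if len(nash) > 1 else 0.0,
                "ratio_nash_over_normal": ratio,
                "t_statistic": float(t_stat),
                "p_value": float(p),
            }
        )
    diff = pd.DataFrame(rows).set_index(["protein", "isoform"])
    p = diff["p_value"].to_numpy()
    if fdr_correction:
        finite = np.isfinite(p)
        adj = np.full_like(p, np.nan)
        if finite.any():
            adj[finite] = multipletests(p[finite], method="fdr_bh")[1]
        diff["p_adjusted"] = adj
        p = adj
    diff["significant"] = np.isfinite(p) & (p <= 0.05)
    diff["degenerate_variance"] = ~np.isfinite(diff["p_value"].to_numpy())
    return diff


def render_heatmaps(
    table: pd.DataFrame, differential: pd.DataFrame, out_dir: str | Path
) -> dict[str, Path]:
    """Write the dual heat maps (PNG) and their lossless CSV twins.

    The concentration map spans [0, 1]; the ratio map shows log2(nash/normal)
    on a symmetric scale with undefined ratios hatched as NA.  CSVs carry the
    exact numbers (17 significant digits).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    conc_csv = out_dir / "isoform_concentrations.csv"
    ratio_csv = out_dir / "isoform_differential.csv"
    table.to_csv(conc_csv, float_format="%.17g")
    differential.to_csv(ratio_csv, float_format="%.17g")

    fig, ax = plt.subplots(figsize=(0.45 * len(table.columns) + 3, 0.3 * len(table) + 2))
    im = ax.imshow(table.to_numpy(), vmin=0, vmax=1, cmap="RdYlGn_r", aspect="auto")
    ax.set_xticks(range(len(table.columns)), table.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(table)), [f"{p}:{i}" for p, i in table.index], fontsize=6)
    fig.colorbar(im, label="relative concentration")
    ax.set_title("Isoform relative concentrations")
    conc_png = out_dir / "isoform_concentrations.png"
    fig.tight_layout()
    fig.savefig(conc_png, dpi=150)
    plt.close(fig)

    ratios = differential["ratio_nash_over_normal"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2r = np.log2(ratios)
    span = np.nanmax(np.abs(log2r[np.isfinite(log2r)])) if np.isfinite(log2r).any() else 1.0
    fig, ax = plt.subplots(figsize=(4, 0.3 * len(differential) + 2))
    masked = np.ma.masked_invalid(log2r[:, None])
    cmap = plt.get_cmap("coolwarm").copy()
    cmap.set_bad(color="0.7")
    im = ax.imshow(masked, vmin=-span, vmax=span, cmap=cmap, aspect="auto")
    ax.set_xticks([])
    ax.set_yticks(range(len(differential)), [f"{p}:{i}" for p, i in differential.index], fontsize=6)
    fig.colorbar(im, label="log2(NASH / normal)")
    ax.set_title("Differential isoform ratio")
    ratio_png = out_dir / "isoform_differential.png"
    fig.tight_layout()
    fig.savefig(ratio_png, dpi=150)
    plt.close(fig)
    return {
        "concentrations_csv": conc_csv,
        "differential_csv": ratio_csv,
        "concentrations_png": conc_png,
        "differential_png": ratio_png,
    }


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits) if np.isfinite(obj) else None
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def full_report(manifest_path: str | Path, out_dir: str | Path) -> dict:
    """Run the complete imaging + proteomics analysis over a cohort on disk.

    Reads the cohort manifest, segments every frame through the phasor
    pipeline, quantifies steatosis and droplets, quantifies every cIEF
    replicate, averages replicate profiles per sample, and writes
    ``report.json`` plus heat maps and a steatosis bar chart.  Output JSON is
    deterministic (sorted keys, rounded floats).

    Raises
    ------
    FileNotFoundError
        If any frame or trace listed in the manifest is missing.
    """
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    missing = []
    for s in manifest["samples"]:
        for fr in s["frames"]:
            if not (root / fr["file"]).exists():
                missing.append(fr["file"])
        for prot in s["cief"].values():
            for rep in prot["replicates"]:
                if not (root / rep["file"]).exists():
                    missing.append(rep["file"])
    if missing:
        raise FileNotFoundError(f"cohort incomplete; missing artifacts: {missing}")

    summaries = {"normal": [], "nash": []}
    sample_entries = []
    profiles: dict[str, dict[str, IsoformProfile]] = {}
    gates = None
    for s in manifest["samples"]:
        frames = []
        for fr in s["frames"]:
            stack = HyperspectralStack.load(root / fr["file"])
            if gates is None:
                gates = default_gates(stack.axis, make_reference_spectra(stack.axis))
            seg = segment_by_gates(phasor_transform(stack), gates)
            comp = percentage_steatosis(seg)
            droplets = detect_droplets(seg, stack.pixel_size)
            frames.append((comp, droplets))
        summary = summarize_sample(frames, s["sample_id"])
        summaries[s["group"]].append(summary)

        profiles[s["sample_id"]] = {}
        for prot, entry in s["cief"].items():
            reps = []
            for rep in entry["replicates"]:
                trace = Electropherogram.load_csv(root / rep["file"])
                reps.append(quantify_trace(trace, protein=prot,
                                           unmodified_pI=entry["unmodified_pI"]))
            mean_conc: dict[str, float] = {}
            for r in reps:
                for iso, v in r.relative_concentration.items():
                    mean_conc[iso] = mean_conc.get(iso, 0.0) + v / len(reps)
            total = sum(mean_conc.values())
            mean_conc = {k: v / total for k, v in mean_conc.items()}
            profiles[s["sample_id"]][prot] = IsoformProfile(
                protein=prot, peaks=reps[0].peaks, relative_concentration=mean_conc
            )
        sample_entries.append(
            {
                "sample_id": s["sample_id"],
                "group": s["group"],
                "steatosis": asdict(summary),
            }
        )

    comparison: GroupComparison = compare_groups(summaries["normal"], summaries["nash"])
    table = build_cohort_table(profiles, manifest)
    differential = differential_analysis(table)
    figures = render_heatmaps(table, differential, out_dir)

    fig, ax = plt.subplots(figsize=(6, 4))
    ordered = summaries["normal"] + summaries["nash"]
    ax.bar(
        [s.sample_id for s in ordered],
        [s.mean_percent_steatosis for s in ordered],
        yerr=[s.sd_percent_steatosis for s in ordered],
        color=["tab:blue"] * len(summaries["normal"]) + ["tab:red"] * len(summaries["nash"]),
    )
    ax.set_ylabel("percentage steatosis (%)")
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    fig.savefig(out_dir / "steatosis_by_sample.png", dpi=150)
    plt.close(fig)

    report = {
        "samples": sample_entries,
        "group_comparison": asdict(comparison),
        "differential": _round_floats(
            differential.reset_index().replace({np.nan: None}).to_dict(orient="records")
        ),
        "figures": {k: str(v.name) for k, v in figures.items()},
    }
    report = _round_floats(report)
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True, allow_nan=False) + "\n"
    )
    return report
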