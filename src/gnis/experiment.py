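"""Orchestration of the full gNIS power experiment.

For every (sample size, replicate) cell of a :class:`~gnis.degradation.GnisDesign`
the engine simulates one degraded dataset, measures diversity (He, I, F_IS),
internal relatedness (correlated per-individual against the full-data truth),
and first/second distance-class spatial autocorrelation with bootstrap
significance, then summarises accuracy (bias versus the full-data truth),
precision (spread across replicates), and the detection rate of positive
genetic structure per sample size.

Seeding is hierarchical: the design's ``master_seed`` spawns one child seed
per (size index, replicate index) through ``numpy``'s SeedSequence spawn-key
mechanism, so any single replicate is reproducible in isolation and results
are independent of execution order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import SnpDataset
from .degradation import GnisDesign, simulate_replicate, subsample_panel
from .filtering import FilterConfig, apply_filters
from .spatial import (
    Correlogram,
    DistanceClassSpec,
    correlogram_from_matrices,
    genetic_distance_matrix,
    geo_distance_matrix,
)
from .stats import (
    DiversityEstimates,
    UndefinedResultError,
    diversity_estimates,
    internal_relatedness,
    pearson_r,
)

logger = logging.getLogger(__name__)

#: distance-class indices reported per replicate (first = 0-250 m, second = 250-500 m)
CLASS_250 = 0
CLASS_500 = 1

RESULT_COLUMNS = [
    "sample_size",
    "replicate",
    "failed",
    "n_loci_post_filter",
    "he",
    "he_spread",
    "ho",
    "shannon",
    "shannon_spread",
    "fis",
    "ir_mean",
    "ir_correlation",
    "r_250",
    "boot_low_250",
    "boot_high_250",
    "significant_250",
    "r_500",
    "boot_low_500",
    "boot_high_500",
    "significant_500",
]


@dataclass
class GroundTruth:
    """Measures of the filtered complete dataset, the reference every
    replicate is compared against."""

    diversity: DiversityEstimates
    ir: pd.Series  # indexed by individual_id
    correlogram: Correlogram
    n_loci_post_filter: int
    dataset: SnpDataset


def ground_truth(
    full_ds: SnpDataset,
    filter_cfg: FilterConfig = FilterConfig(),
    class_spec: DistanceClassSpec = DistanceClassSpec(),
    n_boot: int = 999,
    n_perm: int = 0,
    seed: int = 0,
) -> GroundTruth:
    """Filter the complete dataset and measure everything once."""
    filtered, _ = apply_filters(full_ds, filter_cfg)
    div = diversity_estimates(filtered)
    ir = pd.Series(
        internal_relatedness(filtered),
        index=filtered.individuals["individual_id"].to_numpy(),
    )
    gd = genetic_distance_matrix(filtered)
    geo = geo_distance_matrix(filtered.coordinates)
    corr = correlogram_from_matrices(
        gd, geo, class_spec, n_boot=n_boot, n_perm=n_perm, seed=seed
    )
    return GroundTruth(
        diversity=div,
        ir=ir,
        correlogram=corr,
        n_loci_post_filter=filtered.n_loci,
        dataset=filtered,
    )


def _measure_replicate(
    sim: SnpDataset,
    truth: GroundTruth,
    class_spec: DistanceClassSpec,
    n_boot: int,
    seed,
) -> dict:
    div = diversity_estimates(sim)
    ir = internal_relatedness(sim)
    truth_ir = truth.ir.reindex(sim.individuals["individual_id"]).to_numpy()
    try:
        ir_corr = pearson_r(ir, truth_ir)
    except UndefinedResultError:
        ir_corr = np.nan
    gd = genetic_distance_matrix(sim)
    geo = geo_distance_matrix(sim.coordinates)
    corr = correlogram_from_matrices(gd, geo, class_spec, n_boot=n_boot, seed=seed)
    row = {
        "n_loci_post_filter": sim.n_loci,
        "he": div.he_mean,
        "he_spread": div.he_spread,
        "ho": div.ho_mean,
        "shannon": div.shannon_mean,
        "shannon_spread": div.shannon_spread,
        "fis": div.fis,
        "ir_mean": float(np.nanmean(ir)) if np.isfinite(ir).any() else np.nan,
        "ir_correlation": ir_corr,
    }
    for label, h in (("250", CLASS_250), ("500", CLASS_500)):
        t = corr.table.iloc[h]
        row[f"r_{label}"] = t["r"]
        row[f"boot_low_{label}"] = t["boot_low"]
        row[f"boot_high_{label}"] = t["boot_high"]
        row[f"significant_{label}"] = bool(t["significant_positive"])
    return row


def run_experiment(
    full_ds: SnpDataset,
    design: GnisDesign,
    filter_cfg: FilterConfig = FilterConfig(),
    class_spec: DistanceClassSpec = DistanceClassSpec(),
    n_boot: int = 999,
    out_dir: str | Path | None = None,
    resume: bool = True,
    progress: bool = False,
) -> tuple[pd.DataFrame, "pd.DataFrame"]:
    """Run the full replicate grid; returns (replicate table, summary table).

    With ``out_dir`` set, replicate rows are appended to
    ``out_dir/replicates.csv`` as they complete, a run manifest is written,
    and an interrupted run resumes from the rows already on disk.
    """
    root = np.random.SeedSequence(design.master_seed)
    truth = ground_truth(
        full_ds,
        filter_cfg,
        class_spec,
        n_boot=n_boot,
        seed=np.random.default_rng(np.random.SeedSequence(design.master_seed, spawn_key=(0xFFFF,))),
    )
    # the panel is drawn from the complete *filtered* dataset: loci that
    # failed QC on the full data never enter a simulated panel
    design.validate(truth.dataset)
    within_filtered = subsample_panel(
        truth.dataset, design.panel_size, np.random.default_rng(root.spawn(1)[0])
    )
    kept_ids = truth.dataset.loci["locus_id"].iloc[within_filtered]
    id_to_col = {l: j for j, l in enumerate(full_ds.loci["locus_id"])}
    panel = np.sort(np.array([id_to_col[l] for l in kept_ids]))

    out_path = manifest_path = None
    done: set[tuple[int, int]] = set()
    rows: list[dict] = []
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        out_path = out_dir / "replicates.csv"
        manifest_path = out_dir / "manifest.json"
        manifest = {
            "design": {
                "panel_size": design.panel_size,
                "sample_sizes": list(design.sample_sizes),
                "replicates": design.replicates,
                "profile": asdict(design.profile),
                "master_seed": design.master_seed,
            },
            "filters": asdict(filter_cfg),
            "classes": asdict(class_spec),
            "n_boot": n_boot,
            "truth": asdict(truth.diversity),
        }
        manifest_path.write_text(json.dumps(manifest, indent=2))
        if resume and out_path.exists():
            prev = pd.read_csv(out_path)
            rows = prev.to_dict("records")
            done = {
                (int(r["sample_size"]), int(r["replicate"])) for r in rows
            }
            logger.info("resuming: %d replicates already on disk", len(done))

    for si, size in enumerate(design.sample_sizes):
        for rep in range(design.replicates):
            if (size, rep) in done:
                continue
            ss = np.random.SeedSequence(
                design.master_seed, spawn_key=(si, rep)
            )
            sim_seed, measure_seed = ss.spawn(2)
            row: dict = {"sample_size": size, "replicate": rep, "failed": False}
            sim = simulate_replicate(
                full_ds, panel, size, design.profile, sim_seed, filter_cfg
            )
            if sim.n_loci == 0:
                logger.warning(
                    "size %d replicate %d: zero loci after filtering; "
                    "recorded as failed",
                    size,
                    rep,
                )
                row["failed"] = True
                row.update({k: np.nan for k in RESULT_COLUMNS[3:]})
                row["n_loci_post_filter"] = 0
            else:
                row.update(
                    _measure_replicate(
                        sim,
                        truth,
                        class_spec,
                        n_boot,
                        np.random.default_rng(measure_seed),
                    )
                )
            rows.append(row)
            if out_path is not None:
                pd.DataFrame([row])[RESULT_COLUMNS].to_csv(
                    out_path,
                    mode="a",
                    header=not out_path.exists(),
                    index=False,
                )
            if progress:
                logger.info("size %d replicate %d done", size, rep)

    results = pd.DataFrame(rows)[RESULT_COLUMNS]
    summary = summarize(results, truth)
    if out_dir is not None:
        summary.to_csv(Path(out_dir) / "summary.csv", index=False)
    return results, summary


def summarize(
    results: pd.DataFrame,
    truth: GroundTruth,
    detection_threshold: float = 0.95,
) -> pd.DataFrame:
    """Accuracy / precision / detection summary, one row per sample size.

    Bias is mean(simulated) - truth; precision is the sd across successful
    replicates; detection rate is the fraction of successful replicates whose
    first (or second) distance class shows significant positive structure.
    The threshold size (smallest size whose rate strictly exceeds
    ``detection_threshold``) is attached as DataFrame attrs
    ``threshold_size_250`` / ``threshold_size_500`` (None when never reached).
    """
    ok = results[~results["failed"].astype(bool)]
    rows = []
    for size, grp in ok.groupby("sample_size", sort=True):
        rows.append(
            {
                "sample_size": int(size),
                "n_replicates": len(grp),
                "n_failed": int(
                    (results["sample_size"] == size).sum() - len(grp)
                ),
                "bias_he": grp["he"].mean() - truth.diversity.he_mean,
                "bias_shannon": grp["shannon"].mean() - truth.diversity.shannon_mean,
                "bias_fis": grp["fis"].mean() - truth.diversity.fis,
                "sd_he": grp["he"].std(ddof=1),
                "sd_shannon": grp["shannon"].std(ddof=1),
                "sd_fis": grp["fis"].std(ddof=1),
                "mean_ir_correlation": grp["ir_correlation"].mean(),
                "sd_ir_correlation": grp["ir_correlation"].std(ddof=1),
                "detection_rate_250": grp["significant_250"].astype(float).mean(),
                "detection_rate_500": grp["significant_500"].astype(float).mean(),
            }
        )
    summary = pd.DataFrame(rows)
    for label in ("250", "500"):
        if summary.empty:
            summary.attrs[f"threshold_size_{label}"] = None
            continue
        hit = summary[summary[f"detection_rate_{label}"] > detection_threshold]
        summary.attrs[f"threshold_size_{label}"] = (
            int(hit["sample_size"].iloc[0]) if len(hit) else None
        )
    return summary
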