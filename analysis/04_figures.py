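#!/usr/bin/env python
"""Diagnostic figures for the ground truth and the experiment summary.

Reads the tables written by 02_ground_truth.py and 03_run_experiment.py and
renders: (a) the full-population correlogram with bootstrap error bars and
the permutation null band; (b) detection rate of positive structure vs
sample size for the 250-m and 500-m classes; (c) He bias vs sample size.

Outputs PNGs under results/figures/.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=ROOT / "results")
    args = ap.parse_args()
    figdir = args.results / "figures"
    figdir.mkdir(parents=True, exist_ok=True)

    corr = pd.read_csv(args.results / "ground_truth_correlogram.csv")
    full = corr[corr["group"] == "all"]
    mid = (full["class_lower"] + full["class_upper"]) / 2
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.errorbar(
        mid, full["r"],
        yerr=[full["r"] - full["boot_low"], full["boot_high"] - full["r"]],
        fmt="o-", capsize=3, label="autocorrelation r (95% bootstrap)",
    )
    ax.plot(mid, full["null_low"], "r--", lw=1, label="95% null band")
    ax.plot(mid, full["null_high"], "r--", lw=1)
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel("distance class midpoint (m)")
    ax.set_ylabel("autocorrelation r")
    ax.legend()
    fig.tight_layout()
    fig.savefig(figdir / "correlogram_full_population.png", dpi=150)

    summ = pd.read_csv(args.results / "experiment_summary.csv")
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(summ["sample_size"], summ["detection_rate_250"], "o-", label="250-m class")
    ax.plot(summ["sample_size"], summ["detection_rate_500"], "s-", label="500-m class")
    ax.axhline(0.95, color="grey", ls=":", label="95% of replicates")
    ax.set_xlabel("individuals sampled")
    ax.set_ylabel("replicates with positive structure")
    ax.legend()
    fig.tight_layout()
    fig.savefig(figdir / "detection_rate_vs_sample_size.png", dpi=150)

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.errorbar(summ["sample_size"], summ["bias_he"], yerr=summ["sd_he"],
                fmt="o-", capsize=3)
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel("individuals sampled")
    ax.set_ylabel("He bias (simulated - truth)")
    fig.tight_layout()
    fig.savefig(figdir / "he_bias_vs_sample_size.png", dpi=150)

    print(f"wrote 3 figures to {figdir}")


if __name__ == "__main__":
    main()
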