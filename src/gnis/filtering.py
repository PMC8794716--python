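"""Locus quality-control filters applied to every dataset, complete or simulated.

The pipeline mirrors common reduced-representation QC practice: loci are kept
when reproducibility across technical replicates is at least 95% (inclusive),
call rate is strictly above 70%, minor allele frequency is strictly above 1%,
and secondary SNPs — additional SNPs on an already-represented contig — are
removed so that only one marker per sequenced fragment remains. Filters remove
loci only; they never touch individuals or edit genotype calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import SnpDataset, ValidationError, allele_frequencies, call_rates

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the four-step locus filter.

    ``min_call_rate`` and ``min_maf`` are exclusive bounds (a locus must
    exceed them); ``min_reproducibility`` is inclusive.
    """

    min_call_rate: float = 0.70
    min_maf: float = 0.01
    min_reproducibility: float = 0.95
    drop_secondary: bool = True

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf", "min_reproducibility"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class FilterReport:
    """Per-step accounting of removed loci."""

    n_input: int
    removed: dict[str, int] = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return self.n_input - sum(self.removed.values())


def filter_call_rate(ds: SnpDataset, threshold: float = 0.70) -> SnpDataset:
    """Keep loci whose call rate is strictly greater than *threshold*."""
    keep = call_rates(ds) > threshold
    return ds.take_loci(np.flatnonzero(keep))


def filter_maf(ds: SnpDataset, threshold: float = 0.01) -> SnpDataset:
    """Keep loci whose minor allele frequency (on observed genotypes) is
    strictly greater than *threshold*; loci with no data are removed."""
    p = allele_frequencies(ds)
    with np.errstate(invalid="ignore"):
        maf = np.minimum(p, 1 - p)
        keep = maf > threshold
    return ds.take_loci(np.flatnonzero(keep))


def filter_reproducibility(ds: SnpDataset, threshold: float = 0.95) -> SnpDataset:
    """Keep loci whose reproducibility score is >= *threshold* (inclusive).

    Loci without a score pass with a logged warning, since absence of a
    technical-replicate score is not evidence of irreproducibility.
    """
    scores = ds.loci["reproducibility"].to_numpy(dtype=float)
    absent = np.isnan(scores)
    if absent.any():
        logger.warning(
            "%d loci lack reproducibility scores; retained by default", absent.sum()
        )
    keep = absent | (scores >= threshold)
    return ds.take_loci(np.flatnonzero(keep))


def remove_secondary_snps(ds: SnpDataset) -> SnpDataset:
    """Within each contig keep only the locus with the smallest position
    (ties broken by lexicographic locus ID); drop the rest."""
    tab = ds.loci[["contig_id", "position_in_contig", "locus_id"]].copy()
    tab["_col"] = np.arange(len(tab))
    tab = tab.sort_values(
        ["contig_id", "position_in_contig", "locus_id"], kind="stable"
    )
    first = tab.groupby("contig_id", sort=False).head(1)
    keep = np.sort(first["_col"].to_numpy())
    return ds.take_loci(keep)


def apply_filters(
    ds: SnpDataset, cfg: FilterConfig = FilterConfig()
) -> tuple[SnpDataset, FilterReport]:
    """Run the full pipeline: reproducibility -> call rate -> MAF -> secondary.

    MAF and call rate are computed on the dataset as it stands when the step
    runs, so degradation-induced missingness feeds into both. Returns the
    filtered dataset and a per-step removal report.
    """
    report = FilterReport(n_input=ds.n_loci)
    out = filter_reproducibility(ds, cfg.min_reproducibility)
    report.removed["reproducibility"] = ds.n_loci - out.n_loci

    before = out.n_loci
    out = filter_call_rate(out, cfg.min_call_rate)
    report.removed["call_rate"] = before - out.n_loci

    before = out.n_loci
    out = filter_maf(out, cfg.min_maf)
    report.removed["maf"] = before - out.n_loci

    before = out.n_loci
    if cfg.drop_secondary:
        out = remove_secondary_snps(out)
    report.removed["secondary"] = before - out.n_loci
    return out, report
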