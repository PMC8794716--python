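"""Scalar population- and individual-level genetic measures.

All estimators are computed from the alt-allele dosage matrix on observed
(non-missing) genotypes. Per-locus quantities use the plain 2p(1-p)
convention without the n/(n-1) small-sample correction (available as an
option); the multilocus summaries are means across loci with a spread
reported as sd/sqrt(n_loci) across loci. F_IS is formed from the multilocus
mean He and Ho, not as a mean of per-locus ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import MISSING, SnpDataset, ValidationError, allele_frequencies


class UndefinedResultError(ValueError):
    """Raised when an estimator has no defined value for the given data."""


@dataclass(frozen=True)
class DiversityEstimates:
    """Multilocus diversity summary.

    ``*_spread`` fields are sd/sqrt(n_loci) across loci, the convention
    behind "0.284 +/- 0.002"-style reporting.
    """

    he_mean: float
    he_spread: float
    ho_mean: float
    shannon_mean: float
    shannon_spread: float
    fis: float
    n_loci: int


def _observed_freqs(ds: SnpDataset) -> tuple[np.ndarray, np.ndarray]:
    """(alt-allele frequency, has-data mask) per locus; errors if no locus has data."""
    p = allele_frequencies(ds)
    has_data = ~np.isnan(p)
    if not has_data.any():
        raise UndefinedResultError("no locus has any non-missing genotype")
    return p, has_data


def per_locus_expected_heterozygosity(
    ds: SnpDataset, unbiased: bool = False
) -> np.ndarray:
    """Per-locus He = 2p(1-p) on observed frequencies (NaN where no data).

    ``unbiased=True`` applies the 2n/(2n-1) correction using the per-locus
    observed sample size.
    """
    p = allele_frequencies(ds)
    he = 2.0 * p * (1.0 - p)
    if unbiased:
        n_obs = (ds.genotypes != MISSING).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            he = he * (2.0 * n_obs) / (2.0 * n_obs - 1.0)
    return he


def expected_heterozygosity(
    ds: SnpDataset, unbiased: bool = False
) -> tuple[float, float]:
    """Multilocus mean He and its spread (sd across loci / sqrt(n_loci))."""
    he = per_locus_expected_heterozygosity(ds, unbiased)
    he = he[~np.isnan(he)]
    if he.size == 0:
        raise UndefinedResultError("no locus has any non-missing genotype")
    spread = float(he.std(ddof=1) / np.sqrt(he.size)) if he.size > 1 else 0.0
    return float(he.mean()), spread


def observed_heterozygosity(ds: SnpDataset) -> float:
    """Mean across loci of the fraction of observed genotypes that are
    heterozygous."""
    observed = ds.genotypes != MISSING
    n_obs = observed.sum(axis=0)
    n_het = (ds.genotypes == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = n_het / n_obs
    ho = ho[n_obs > 0]
    if ho.size == 0:
        raise UndefinedResultError("no locus has any non-missing genotype")
    return float(ho.mean())


def shannon_index(ds: SnpDataset) -> tuple[float, float]:
    """Shannon's information index I = -[p ln p + (1-p) ln(1-p)] per locus,
    averaged over loci (natural log; monomorphic loci contribute 0)."""
    p, has_data = _observed_freqs(ds)
    p = p[has_data]
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = -(
            np.where(p > 0, p * np.log(p), 0.0)
            + np.where(p < 1, (1 - p) * np.log(1 - p), 0.0)
        )
    spread = float(terms.std(ddof=1) / np.sqrt(terms.size)) if terms.size > 1 else 0.0
    return float(terms.mean()), spread


def inbreeding_coefficient(ds: SnpDataset) -> float:
    """F_IS = (He - Ho) / He from the multilocus mean He and Ho."""
    he, _ = expected_heterozygosity(ds)
    if he == 0:
        raise UndefinedResultError("He is zero; F_IS undefined")
    ho = observed_heterozygosity(ds)
    return (he - ho) / he


def diversity_estimates(ds: SnpDataset) -> DiversityEstimates:
    """All multilocus diversity measures in one pass."""
    he, he_spread = expected_heterozygosity(ds)
    ho = observed_heterozygosity(ds)
    sh, sh_spread = shannon_index(ds)
    fis = (he - ho) / he if he > 0 else np.nan
    p = allele_frequencies(ds)
    return DiversityEstimates(
        he_mean=he,
        he_spread=he_spread,
        ho_mean=ho,
        shannon_mean=sh,
        shannon_spread=sh_spread,
        fis=float(fis),
        n_loci=int((~np.isnan(p)).sum()),
    )


def internal_relatedness(
    ds: SnpDataset,
    include_self: bool = True,
    freqs: np.ndarray | None = None,
) -> np.ndarray:
    """Internal relatedness per individual: IR = (2H - sum f_i) / (2N - sum f_i).

    H is the individual's count of homozygous loci, N its count of non-missing
    loci, and sum f_i the summed population frequencies of its 2N allele
    copies, computed from this same dataset (a cohort-relative measure). With
    ``include_self=False`` the focal individual's own alleles are excluded
    from the frequency estimates; *freqs* supplies externally known alt-allele
    frequencies instead of estimating them from the cohort. Individuals with
    no non-missing loci get NaN.
    """
    geno = ds.genotypes.astype(float)
    observed = ds.genotypes != MISSING
    n_obs_per_locus = observed.sum(axis=0)
    alt_per_locus = np.where(observed, ds.genotypes, 0).sum(axis=0)

    H = ((ds.genotypes == 0) | (ds.genotypes == 2)).sum(axis=1).astype(float)
    N = observed.sum(axis=1).astype(float)

    if freqs is not None and not include_self:
        raise ValidationError("freqs and include_self=False are mutually exclusive")
    if include_self:
        if freqs is not None:
            p = np.asarray(freqs, dtype=float)
            if p.shape != (ds.n_loci,):
                raise ValidationError("freqs must have one value per locus")
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                p = alt_per_locus / (2.0 * n_obs_per_locus)
        g = np.where(observed, geno, 0.0)
        # per copy pair: genotype 0 -> 2(1-p), 1 -> 1, 2 -> 2p
        sum_f = (observed * (2.0 * (1.0 - p)[None, :] + g * (2.0 * p - 1.0)[None, :])).sum(
            axis=1
        )
    else:
        # leave-one-out frequencies differ per focal individual
        alt_loo = alt_per_locus[None, :] - np.where(observed, geno, 0.0)
        n_loo = n_obs_per_locus[None, :] - observed
        with np.errstate(invalid="ignore", divide="ignore"):
            p_loo = alt_loo / (2.0 * n_loo)
        p_loo = np.where(n_loo > 0, p_loo, np.nan)
        g = np.where(observed, geno, 0.0)
        contrib = 2.0 * (1.0 - p_loo) + g * (2.0 * p_loo - 1.0)
        usable = observed & ~np.isnan(p_loo)
        sum_f = np.where(usable, contrib, 0.0).sum(axis=1)
        H = (usable & ((ds.genotypes == 0) | (ds.genotypes == 2))).sum(axis=1).astype(float)
        N = usable.sum(axis=1).astype(float)

    denom = 2.0 * N - sum_f
    with np.errstate(invalid="ignore", divide="ignore"):
        ir = (2.0 * H - sum_f) / denom
    ir = np.where((N > 0) & (np.abs(denom) > 1e-12), ir, np.nan)
    return ir


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation on pairwise-complete entries (needs >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        raise UndefinedResultError(
            f"need >= 3 paired non-missing values, got {int(ok.sum())}"
        )
    xv, yv = x[ok] - x[ok].mean(), y[ok] - y[ok].mean()
    denom = np.sqrt((xv**2).sum() * (yv**2).sum())
    if denom == 0:
        raise UndefinedResultError("zero variance in one of the vectors")
    return float((xv * yv).sum() / denom)
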