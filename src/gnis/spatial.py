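"""Multilocus spatial autocorrelation of genetic vs geographic distance.

Implements the Smouse-Peakall multivariate autocorrelation framework for
codominant biallelic data: pairwise squared genetic distances are
double-centered into a covariance-like matrix ``c = -1/2 J D2 J`` and, within
each geographic distance class h, the autocorrelation coefficient is

    r_h = sum over pairs (x, y) in class h of c_xy
          / sum over the same pairs of (c_xx + c_yy) / 2 .

Significance is assessed two ways: a 95% bootstrap confidence interval around
r_h (resampling pairs within each class, 999 iterations by default) and a
permutation null obtained by shuffling individual coordinates (random
geographic arrangement). A class shows significant positive structure when
r_h > 0 and the bootstrap CI excludes zero from below.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import MISSING, SnpDataset, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DistanceClassSpec:
    """Half-open distance classes [k*w, (k+1)*w) tiling [0, max_distance)."""

    class_width: float = 250.0
    max_distance: float = 3500.0

    def __post_init__(self) -> None:
        if self.class_width <= 0 or self.max_distance <= 0:
            raise ValidationError("class_width and max_distance must be positive")

    @property
    def n_classes(self) -> int:
        return int(np.ceil(self.max_distance / self.class_width))

    @property
    def edges(self) -> np.ndarray:
        return np.arange(self.n_classes + 1) * self.class_width

    def midpoints(self) -> np.ndarray:
        e = self.edges
        return (e[:-1] + e[1:]) / 2.0


@dataclass
class Correlogram:
    """Per-distance-class autocorrelation results.

    ``table`` has one row per class with columns ``class_lower``,
    ``class_upper``, ``n_pairs``, ``r``, ``boot_low``, ``boot_high``,
    ``null_low``, ``null_high`` and ``significant_positive``. Classes with no
    pairs carry NaN and are flagged by ``n_pairs == 0``.
    """

    table: pd.DataFrame

    def r(self, class_index: int) -> float:
        return float(self.table["r"].iloc[class_index])

    def significant_positive(self, class_index: int) -> bool:
        return bool(self.table["significant_positive"].iloc[class_index])


def geo_distance_matrix(coords: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances (metres) on planar coordinates."""
    coords = np.asarray(coords, dtype=float)
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def genetic_distance_matrix(ds: SnpDataset) -> np.ndarray:
    """Pairwise squared genetic distances for codominant biallelic loci.

    Per locus the squared distance between dosages is (g1 - g2)^2, i.e. 0 for
    identical genotypes, 1 for homozygote vs heterozygote, 4 for opposite
    homozygotes; summed over loci observed in BOTH individuals and rescaled by
    (total loci / shared loci) so that pairs with heavy missingness are not
    artificially close. Pairs sharing no locus get NaN (excluded, logged).
    """
    observed = (ds.genotypes != MISSING).astype(float)
    g = np.where(ds.genotypes != MISSING, ds.genotypes, 0).astype(float)
    g2 = g**2
    shared = observed @ observed.T
    raw = (g2 * observed) @ observed.T + observed @ (g2 * observed).T - 2.0 * (g @ g.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = raw * (ds.n_loci / shared)
    none_shared = shared == 0
    if none_shared.any():
        n_pairs = (none_shared.sum() - np.diag(none_shared).sum()) // 2
        if n_pairs:
            logger.warning("%d pairs share no non-missing locus; excluded", n_pairs)
        d2[none_shared] = np.nan
    np.fill_diagonal(d2, 0.0)
    # numerical symmetry
    return (d2 + d2.T) / 2.0


def _center(d2: np.ndarray) -> np.ndarray:
    """Gower double-centering: c = -1/2 J d2 J."""
    d2 = np.asarray(d2, dtype=float)
    if np.isnan(d2).any():
        fill = np.nanmean(d2[~np.eye(len(d2), dtype=bool)])
        logger.warning("NaN genetic distances imputed with the mean for centering")
        d2 = np.where(np.isnan(d2), fill, d2)
    row = d2.mean(axis=1, keepdims=True)
    grand = d2.mean()
    return -0.5 * (d2 - row - row.T + grand)


def _class_arrays(
    c: np.ndarray, geo: np.ndarray, spec: DistanceClassSpec
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per class: (off-diagonal c values, paired mean diagonal values)."""
    n = len(c)
    iu, ju = np.triu_indices(n, k=1)
    dist = geo[iu, ju]
    cls = np.floor(dist / spec.class_width).astype(int)
    valid = dist < spec.max_distance
    diag = np.diag(c)
    nums, dens = [], []
    for h in range(spec.n_classes):
        m = valid & (cls == h)
        nums.append(c[iu[m], ju[m]])
        dens.append((diag[iu[m]] + diag[ju[m]]) / 2.0)
    return nums, dens


def _r_from_arrays(nums: list[np.ndarray], dens: list[np.ndarray]) -> np.ndarray:
    r = np.full(len(nums), np.nan)
    for h, (a, b) in enumerate(zip(nums, dens)):
        if a.size and abs(b.sum()) > 1e-300:
            r[h] = a.sum() / b.sum()
    return r


def autocorrelation_r(
    gd: np.ndarray, geo: np.ndarray, spec: DistanceClassSpec = DistanceClassSpec()
) -> np.ndarray:
    """Per-class autocorrelation r from matched genetic (squared) and
    geographic distance matrices; NaN for empty classes."""
    if gd.shape != geo.shape:
        raise ValidationError("genetic and geographic matrices must match")
    c = _center(gd)
    nums, dens = _class_arrays(c, geo, spec)
    return _r_from_arrays(nums, dens)


def bootstrap_r_ci(
    gd: np.ndarray,
    geo: np.ndarray,
    spec: DistanceClassSpec = DistanceClassSpec(),
    n_boot: int = 999,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    return_samples: bool = False,
) -> np.ndarray | tuple[np.ndarray, list[np.ndarray]]:
    """95% bootstrap CI per class: resample pairs within class with
    replacement, recompute r, take the alpha/2 and 1-alpha/2 percentiles.

    Returns an (n_classes, 2) array of (low, high); NaN for empty classes.
    With ``return_samples=True`` also returns the per-class arrays of
    resampled r values (length ``n_boot`` for non-empty classes).
    """
    rng = np.random.default_rng(seed)
    c = _center(gd)
    nums, dens = _class_arrays(c, geo, spec)
    out = np.full((spec.n_classes, 2), np.nan)
    samples: list[np.ndarray] = []
    for h, (a, b) in enumerate(zip(nums, dens)):
        m = a.size
        if m == 0:
            samples.append(np.empty(0))
            continue
        rs = np.empty(n_boot)
        # chunked to bound the (chunk, m) index array
        chunk = max(1, int(5e6 // max(m, 1)))
        done = 0
        while done < n_boot:
            k = min(chunk, n_boot - done)
            idx = rng.integers(0, m, size=(k, m))
            num = a[idx].sum(axis=1)
            den = b[idx].sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                rs[done : done + k] = num / den
            done += k
        samples.append(rs)
        rs = rs[~np.isnan(rs)]
        if rs.size:
            out[h] = np.percentile(rs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    if return_samples:
        return out, samples
    return out


def permutation_null_ci(
    gd: np.ndarray,
    geo: np.ndarray,
    spec: DistanceClassSpec = DistanceClassSpec(),
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Null 95% bounds per class under random geographic arrangement:
    permute coordinates among individuals, recompute r, take percentiles."""
    rng = np.random.default_rng(seed)
    n = len(gd)
    c = _center(gd)
    iu, ju = np.triu_indices(n, k=1)
    c_pairs = c[iu, ju]
    diag = np.diag(c)
    d_pairs = (diag[iu] + diag[ju]) / 2.0
    rs = np.full((n_perm, spec.n_classes), np.nan)
    for t in range(n_perm):
        perm = rng.permutation(n)
        dist = geo[perm[iu], perm[ju]]
        cls = np.floor(dist / spec.class_width).astype(int)
        valid = dist < spec.max_distance
        cls_v = cls[valid]
        num = np.bincount(cls_v, weights=c_pairs[valid], minlength=spec.n_classes)
        den = np.bincount(cls_v, weights=d_pairs[valid], minlength=spec.n_classes)
        count = np.bincount(cls_v, minlength=spec.n_classes)
        with np.errstate(invalid="ignore", divide="ignore"):
            row = num / den
        rs[t] = np.where(count > 0, row, np.nan)
    out = np.full((spec.n_classes, 2), np.nan)
    for h in range(spec.n_classes):
        col = rs[:, h]
        col = col[~np.isnan(col)]
        if col.size:
            out[h] = np.percentile(col, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return out


def detect_positive_structure(corr: Correlogram, class_of_interest: int) -> bool:
    """True iff r > 0 and the bootstrap CI lower bound is > 0 for the class."""
    row = corr.table.iloc[class_of_interest]
    return bool(
        np.isfinite(row["r"])
        and row["r"] > 0
        and np.isfinite(row["boot_low"])
        and row["boot_low"] > 0
    )


def correlogram_from_matrices(
    gd: np.ndarray,
    geo: np.ndarray,
    spec: DistanceClassSpec = DistanceClassSpec(),
    n_boot: int = 999,
    n_perm: int = 0,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> Correlogram:
    """Full correlogram from precomputed matrices; ``n_perm=0`` skips the
    permutation null (NaN bounds)."""
    rng = np.random.default_rng(seed)
    r = autocorrelation_r(gd, geo, spec)
    boot = bootstrap_r_ci(gd, geo, spec, n_boot=n_boot, alpha=alpha, seed=rng)
    null = (
        permutation_null_ci(gd, geo, spec, n_perm=n_perm, alpha=alpha, seed=rng)
        if n_perm
        else np.full((spec.n_classes, 2), np.nan)
    )
    n = len(gd)
    iu, ju = np.triu_indices(n, k=1)
    dist = geo[iu, ju]
    cls = np.floor(dist / spec.class_width).astype(int)
    valid = dist < spec.max_distance
    counts = np.bincount(cls[valid], minlength=spec.n_classes)[: spec.n_classes]
    edges = spec.edges
    table = pd.DataFrame(
        {
            "class_lower": edges[:-1],
            "class_upper": edges[1:],
            "n_pairs": counts,
            "r": r,
            "boot_low": boot[:, 0],
            "boot_high": boot[:, 1],
            "null_low": null[:, 0],
            "null_high": null[:, 1],
        }
    )
    table["significant_positive"] = (
        np.isfinite(table["r"])
        & (table["r"] > 0)
        & np.isfinite(table["boot_low"])
        & (table["boot_low"] > 0)
    )
    return Correlogram(table)


def correlogram(
    ds: SnpDataset,
    spec: DistanceClassSpec = DistanceClassSpec(),
    grouping: str = "all",
    n_boot: int = 999,
    n_perm: int = 0,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> dict[str, Correlogram]:
    """Correlogram(s) for a dataset: ``grouping="all"`` pools everyone,
    ``"by_sex"`` runs males and females separately (groups with fewer than 3
    individuals are skipped with a warning)."""
    rng = np.random.default_rng(seed)
    if grouping == "all":
        groups = {"all": np.arange(ds.n_individuals)}
    elif grouping == "by_sex":
        sexes = ds.individuals["sex"].to_numpy()
        groups = {
            sex: np.flatnonzero(sexes == sex)
            for sex in ("male", "female")
            if (sexes == sex).any()
        }
        n_unknown = int((sexes == "unknown").sum())
        if n_unknown:
            logger.warning("%d individuals of unknown sex excluded", n_unknown)
    else:
        raise ValidationError(f"unknown grouping {grouping!r}")
    out: dict[str, Correlogram] = {}
    for name, idx in groups.items():
        if len(idx) < 3:
            logger.warning("group %r has %d individuals (<3); skipped", name, len(idx))
            continue
        sub = ds.take_individuals(idx)
        gd = genetic_distance_matrix(sub)
        geo = geo_distance_matrix(sub.coordinates)
        out[name] = correlogram_from_matrices(
            gd, geo, spec, n_boot=n_boot, n_perm=n_perm, alpha=alpha, seed=rng
        )
    return out
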