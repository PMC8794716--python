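"""Core container for biallelic SNP genotype matrices with locus and individual metadata.

Genotypes are stored as alt-allele dosage (0, 1, 2) in an ``int8`` matrix with
``MISSING`` (-1) as the missing-data sentinel. Rows are individuals, columns are
loci. Locus metadata (contig assignment, position within contig, reproducibility
score from technical replicates) and individual metadata (sex, planar capture
coordinates in metres) travel with the matrix so that every pipeline stage —
filtering, subsampling, degradation, measurement — consumes and returns the same
object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call in the dosage matrix.
MISSING: int = -1

VALID_SEXES = ("male", "female", "unknown")

LOCUS_COLUMNS = ["locus_id", "contig_id", "position_in_contig", "reproducibility"]
INDIVIDUAL_COLUMNS = ["individual_id", "sex", "x", "y"]


class ValidationError(ValueError):
    """Raised when a dataset violates its structural invariants."""


@dataclass
class SnpDataset:
    """Biallelic SNP dataset: dosage matrix plus aligned metadata tables.

    Parameters
    ----------
    genotypes
        ``(n_individuals, n_loci)`` integer matrix of alt-allele dosages with
        values in {0, 1, 2, MISSING}.
    loci
        DataFrame with columns ``locus_id``, ``contig_id``,
        ``position_in_contig`` and ``reproducibility`` (NaN when no technical
        replicate score is available), one row per matrix column.
    individuals
        DataFrame with columns ``individual_id``, ``sex`` (``male`` /
        ``female`` / ``unknown``) and planar coordinates ``x``, ``y`` in
        metres, one row per matrix row.
    """

    genotypes: np.ndarray
    loci: pd.DataFrame
    individuals: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValidationError("genotype matrix must be 2-dimensional")
        self.loci = self.loci.reset_index(drop=True)
        self.individuals = self.individuals.reset_index(drop=True)
        self.validate()

    # -- invariants -------------------------------------------------------

    def validate(self) -> None:
        n_ind, n_loc = self.genotypes.shape
        if len(self.individuals) != n_ind:
            raise ValidationError(
                f"matrix has {n_ind} rows but {len(self.individuals)} individual records"
            )
        if len(self.loci) != n_loc:
            raise ValidationError(
                f"matrix has {n_loc} columns but {len(self.loci)} locus records"
            )
        for col in LOCUS_COLUMNS:
            if col not in self.loci.columns:
                raise ValidationError(f"loci table missing column {col!r}")
        for col in INDIVIDUAL_COLUMNS:
            if col not in self.individuals.columns:
                raise ValidationError(f"individuals table missing column {col!r}")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"invalid genotype value {int(self.genotypes[i, j])} at "
                f"individual row {i}, locus column {j}"
            )
        if self.loci["locus_id"].duplicated().any():
            dup = self.loci["locus_id"][self.loci["locus_id"].duplicated()].iloc[0]
            raise ValidationError(f"duplicate locus ID {dup!r}")
        if self.individuals["individual_id"].duplicated().any():
            dup = self.individuals["individual_id"][
                self.individuals["individual_id"].duplicated()
            ].iloc[0]
            raise ValidationError(f"duplicate individual ID {dup!r}")
        if not self.individuals["sex"].isin(VALID_SEXES).all():
            bad_sex = self.individuals["sex"][
                ~self.individuals["sex"].isin(VALID_SEXES)
            ].iloc[0]
            raise ValidationError(f"invalid sex value {bad_sex!r}")
        coords = self.individuals[["x", "y"]].to_numpy(dtype=float)
        if coords.size and not np.isfinite(coords).all():
            raise ValidationError("individual coordinates must be finite")
        pos = self.loci["position_in_contig"].to_numpy()
        if len(pos) and (pos < 0).any():
            raise ValidationError("position_in_contig must be non-negative")
        repro = self.loci["reproducibility"].to_numpy(dtype=float)
        ok = np.isnan(repro) | ((repro >= 0) & (repro <= 1))
        if not ok.all():
            raise ValidationError("reproducibility scores must lie in [0, 1]")

    # -- shape ------------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def coordinates(self) -> np.ndarray:
        """``(n_individuals, 2)`` array of planar coordinates in metres."""
        return self.individuals[["x", "y"]].to_numpy(dtype=float)

    # -- subsetting -------------------------------------------------------

    def take_individuals(self, index: np.ndarray) -> "SnpDataset":
        """Row subset (or reorder) by positional index; locus set unchanged."""
        index = np.asarray(index, dtype=int)
        return SnpDataset(
            self.genotypes[index, :].copy(),
            self.loci.copy(),
            self.individuals.iloc[index].reset_index(drop=True),
        )

    def take_loci(self, index: np.ndarray) -> "SnpDataset":
        """Column subset (or reorder) by positional index; individuals unchanged."""
        index = np.asarray(index, dtype=int)
        return SnpDataset(
            self.genotypes[:, index].copy(),
            self.loci.iloc[index].reset_index(drop=True),
            self.individuals.copy(),
        )

    def copy(self) -> "SnpDataset":
        return SnpDataset(
            self.genotypes.copy(), self.loci.copy(), self.individuals.copy()
        )

    def equals(self, other: "SnpDataset") -> bool:
        """Exact equality of genotypes and metadata (NaN-tolerant on reproducibility)."""
        if self.genotypes.shape != other.genotypes.shape:
            return False
        if not np.array_equal(self.genotypes, other.genotypes):
            return False
        a, b = self.loci, other.loci
        if not (
            a["locus_id"].equals(b["locus_id"])
            and a["contig_id"].equals(b["contig_id"])
            and np.array_equal(
                a["position_in_contig"].to_numpy(int),
                b["position_in_contig"].to_numpy(int),
            )
            and np.allclose(
                a["reproducibility"].to_numpy(float),
                b["reproducibility"].to_numpy(float),
                equal_nan=True,
            )
        ):
            return False
        c, d = self.individuals, other.individuals
        return bool(
            c["individual_id"].equals(d["individual_id"])
            and c["sex"].equals(d["sex"])
            and np.allclose(c[["x", "y"]].to_numpy(float), d[["x", "y"]].to_numpy(float))
        )


def call_rates(ds: SnpDataset) -> np.ndarray:
    """Per-locus call rate: fraction of individuals with a non-missing genotype.

    Requires at least one individual; values lie in [0, 1].
    """
    if ds.n_individuals == 0:
        raise ValidationError("call rates undefined for a dataset with no individuals")
    return (ds.genotypes != MISSING).mean(axis=0)


def allele_frequencies(ds: SnpDataset) -> np.ndarray:
    """Per-locus alt-allele frequency on observed (non-missing) genotypes.

    A locus with no non-missing genotypes yields NaN (undefined).
    """
    observed = ds.genotypes != MISSING
    n_obs = observed.sum(axis=0)
    alt = np.where(observed, ds.genotypes, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = alt / (2.0 * n_obs)
    freq = np.where(n_obs > 0, freq, np.nan)
    return freq
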