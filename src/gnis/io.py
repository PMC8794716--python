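"""Readers and writers for the genotype CSV dialect and VCF interchange.

CSV dialect
-----------
A dataset is a trio of UTF-8 comma-separated files sharing a prefix:

``<prefix>.csv``
    Header row: ``individual_id`` followed by locus IDs. One row per
    individual, genotypes as alt-allele dosage 0/1/2 with a configurable
    missing sentinel (default ``"NA"``).
``<prefix>.loci.csv``
    Columns ``locus_id, contig_id, position_in_contig, reproducibility``
    (reproducibility may be empty when no technical-replicate score exists).
``<prefix>.individuals.csv``
    Columns ``individual_id, sex, x, y`` (coordinates in planar metres).

VCF interchange uses VCF 4.2, biallelic sites only: GT 0/0 -> 0, 0/1 -> 1,
1/1 -> 2, ./. -> missing; CHROM becomes ``contig_id`` and POS (1-based, copied
verbatim) becomes ``position_in_contig``. Multiallelic records are skipped
with a warning.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import (
    INDIVIDUAL_COLUMNS,
    LOCUS_COLUMNS,
    MISSING,
    SnpDataset,
    ValidationError,
)

logger = logging.getLogger(__name__)

DEFAULT_MISSING_TOKEN = "NA"


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted."""


def _companion_paths(path: str | Path) -> tuple[Path, Path, Path]:
    path = Path(path)
    stem = path.with_suffix("")
    return path, stem.with_suffix(".loci.csv"), stem.with_suffix(".individuals.csv")


def write_genotype_csv(
    ds: SnpDataset, path: str | Path, missing_token: str = DEFAULT_MISSING_TOKEN
) -> None:
    """Write the CSV trio for *ds* under the prefix implied by *path*."""
    geno_path, loci_path, ind_path = _companion_paths(path)
    geno = ds.genotypes.astype(object)
    geno[ds.genotypes == MISSING] = missing_token
    table = pd.DataFrame(geno, columns=ds.loci["locus_id"].tolist())
    table.insert(0, "individual_id", ds.individuals["individual_id"].to_numpy())
    table.to_csv(geno_path, index=False)
    ds.loci[LOCUS_COLUMNS].to_csv(loci_path, index=False)
    ds.individuals[INDIVIDUAL_COLUMNS].to_csv(ind_path, index=False)


def read_genotype_csv(
    path: str | Path, missing_token: str = DEFAULT_MISSING_TOKEN
) -> SnpDataset:
    """Read the CSV trio written by :func:`write_genotype_csv` into a dataset."""
    geno_path, loci_path, ind_path = _companion_paths(path)
    table = pd.read_csv(geno_path, dtype=str, keep_default_na=False)
    if table.columns[0] != "individual_id":
        raise ParseError(
            f"{geno_path}: first column must be 'individual_id', got {table.columns[0]!r}"
        )
    locus_ids = list(table.columns[1:])
    raw = table[locus_ids].to_numpy(dtype=object)
    geno = np.empty(raw.shape, dtype=np.int8)
    for tok, value in ((missing_token, MISSING), ("0", 0), ("1", 1), ("2", 2)):
        geno[raw == tok] = value
    recognised = np.isin(raw, (missing_token, "0", "1", "2"))
    if not recognised.all():
        i, j = np.argwhere(~recognised)[0]
        raise ParseError(
            f"{geno_path}: invalid genotype token {raw[i, j]!r} at row "
            f"{i + 2} (individual {table.iloc[i, 0]!r}), column {locus_ids[j]!r}"
        )

    loci = pd.read_csv(loci_path)
    individuals = pd.read_csv(ind_path)
    missing_loci = [c for c in LOCUS_COLUMNS if c not in loci.columns]
    if missing_loci:
        raise ParseError(f"{loci_path}: missing columns {missing_loci}")
    missing_ind = [c for c in INDIVIDUAL_COLUMNS if c not in individuals.columns]
    if missing_ind:
        raise ParseError(f"{ind_path}: missing columns {missing_ind}")
    loci = loci.copy()
    loci["locus_id"] = loci["locus_id"].astype(str)
    loci["contig_id"] = loci["contig_id"].astype(str)
    individuals = individuals.copy()
    individuals["individual_id"] = individuals["individual_id"].astype(str)
    if list(loci["locus_id"]) != locus_ids:
        raise ParseError(
            f"{loci_path}: locus IDs do not match the genotype file header order"
        )
    if list(individuals["individual_id"]) != list(table["individual_id"]):
        raise ParseError(
            f"{ind_path}: individual IDs do not match the genotype file rows"
        )
    try:
        return SnpDataset(geno, loci, individuals)
    except ValidationError as exc:
        raise ValidationError(f"{geno_path}: {exc}") from exc


# -- VCF ------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=gnis
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(ds: SnpDataset, path: str | Path) -> None:
    """Write *ds* as an uncompressed biallelic VCF 4.2 file.

    Reproducibility scores are carried in an ``RP`` INFO tag so that a
    VCF round trip preserves them; capture coordinates are not representable
    in VCF and are dropped (CSV is the lossless format).
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_VCF_HEADER)
        fh.write(
            '##INFO=<ID=RP,Number=1,Type=Float,Description="Locus reproducibility">\n'
        )
        for contig in pd.unique(ds.loci["contig_id"]):
            fh.write(f"##contig=<ID={contig}>\n")
        sample_ids = "\t".join(ds.individuals["individual_id"])
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_ids + "\n"
        )
        # loci sorted by (contig, position) per VCF convention
        order = np.lexsort(
            (
                ds.loci["position_in_contig"].to_numpy(),
                ds.loci["contig_id"].to_numpy(),
            )
        )
        for j in order:
            row = ds.loci.iloc[j]
            repro = row["reproducibility"]
            info = "." if pd.isna(repro) else f"RP={repro:g}"
            calls = "\t".join(_GT_STRINGS[int(g)] for g in ds.genotypes[:, j])
            fh.write(
                f"{row['contig_id']}\t{int(row['position_in_contig'])}\t"
                f"{row['locus_id']}\tA\tG\t.\tPASS\t{info}\tGT\t{calls}\n"
            )


def read_vcf(path: str | Path) -> SnpDataset:
    """Read a biallelic VCF into a dataset; multiallelic sites are skipped."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: list[dict] = []
    columns: list[np.ndarray] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            msg = (
                f"skipping multiallelic site {variant.CHROM}:{variant.POS} "
                f"(ALT={variant.ALT})"
            )
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = variant.gt_types
        dosage = np.select(
            [gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING
        ).astype(np.int8)
        repro = variant.INFO.get("RP")
        rows.append(
            {
                "locus_id": variant.ID
                if variant.ID
                else f"{variant.CHROM}:{variant.POS}",
                "contig_id": variant.CHROM,
                "position_in_contig": variant.POS,
                "reproducibility": np.nan if repro is None else float(repro),
            }
        )
        columns.append(dosage)
    vcf.close()
    geno = (
        np.column_stack(columns)
        if columns
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    loci = pd.DataFrame(rows, columns=LOCUS_COLUMNS)
    individuals = pd.DataFrame(
        {
            "individual_id": samples,
            "sex": "unknown",
            "x": 0.0,
            "y": 0.0,
        }
    )
    return SnpDataset(geno, loci, individuals)
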