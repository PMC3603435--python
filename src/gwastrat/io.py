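"""Readers and writers for the text formats the pipeline consumes.

PLINK text dialect
------------------
``.map``: four whitespace-separated columns per SNP —
chromosome, snp_id, genetic distance (written as 0), bp position.

``.ped``: six leading columns per sample —
family id, individual id, father (0), mother (0), sex in {1,2},
phenotype placeholder (-9) — followed by two allele characters per SNP;
a missing genotype is ``0 0``.

The .map file carries no allele labels, so on read A1 is oriented to the
empirically minor allele (ties broken alphabetically); the writer applies
the same rule before emitting, which makes write -> read an exact
round-trip of the dosage matrix.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    SAMPLE_COLUMNS,
    TRAITS,
    DataError,
    GenotypeMatrix,
    validate_sample_table,
)

_SEX_CODE = {"male": 1, "female": 2}
_SEX_LABEL = {1: "male", 2: "female"}


def _minor_first(counts: dict[str, int]) -> tuple[str, str]:
    """Order two allele labels as (minor, major); ties alphabetical."""
    alleles = sorted(counts)  # alphabetical, then stable sort by count
    alleles.sort(key=lambda al: counts[al])
    if len(alleles) == 1:
        other = "A" if alleles[0] != "A" else "B"
        return alleles[0], other
    return alleles[0], alleles[1]


def write_plink_text(G: GenotypeMatrix, S: pd.DataFrame, prefix) -> list[Path]:
    """Write ``<prefix>.ped``, ``<prefix>.map`` and ``<prefix>.pheno.tsv``.

    A1 is re-oriented to the within-sample minor allele before writing so
    the output round-trips losslessly through :func:`read_plink_text`.
    Returns the paths written.
    """
    S = validate_sample_table(S)
    if not np.array_equal(S["sample_id"].to_numpy(dtype=object), G.sample_ids):
        raise DataError("sample ids of genotype matrix and sample table differ")
    prefix = Path(prefix)
    os.makedirs(prefix.parent, exist_ok=True)

    dosage = G.dosage.copy()
    a1 = G.snp_meta["a1"].to_numpy(dtype=object).copy()
    a2 = G.snp_meta["a2"].to_numpy(dtype=object).copy()
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dosage, axis=0) / 2.0
    freq = np.where(np.isnan(freq), 0.0, freq)
    flip = (freq > 0.5) | ((freq == 0.5) & (a1 > a2))
    dosage[:, flip] = 2.0 - dosage[:, flip]
    a1[flip], a2[flip] = a2[flip].copy(), a1[flip].copy()

    map_path = prefix.with_suffix(".map")
    with open(map_path, "w") as fh:
        for _, row in G.snp_meta.iterrows():
            fh.write(f"{row['chrom']}\t{row['snp_id']}\t0\t{row['pos']}\n")

    ped_path = prefix.with_suffix(".ped")
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(G.sample_ids):
            sex = _SEX_CODE[S.loc[i, "sex"]]
            fields = [str(sid), str(sid), "0", "0", str(sex), "-9"]
            row = dosage[i]
            for j in range(G.n_snps):
                d = row[j]
                if np.isnan(d):
                    fields += ["0", "0"]
                elif d == 2:
                    fields += [a1[j], a1[j]]
                elif d == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a2[j], a2[j]]
            fh.write(" ".join(fields) + "\n")

    pheno_path = Path(str(prefix) + ".pheno.tsv")
    out = S.copy()
    out["sex"] = out["sex"].map(_SEX_CODE)
    out.to_csv(pheno_path, sep="\t", index=False, na_rep="NA")
    return [ped_path, map_path, pheno_path]


def read_plink_text(prefix) -> GenotypeMatrix:
    """Read ``<prefix>.ped`` / ``<prefix>.map`` into a GenotypeMatrix."""
    prefix = Path(prefix)
    snp_meta = pd.read_csv(
        prefix.with_suffix(".map"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos"],
        dtype={"chrom": str, "snp_id": str},
    )
    n_snps = len(snp_meta)

    sample_ids: list[str] = []
    allele_rows: list[list[str]] = []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise DataError(
                    f".ped row for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts)} fields, expected {6 + 2 * n_snps}"
                )
            sample_ids.append(parts[1])
            allele_rows.append(parts[6:])

    n = len(sample_ids)
    alleles = np.array(allele_rows, dtype=object).reshape(n, n_snps, 2)
    dosage = np.full((n, n_snps), np.nan)
    a1_list, a2_list = [], []
    for j in range(n_snps):
        col = alleles[:, j, :]
        observed = col[col != "0"]
        counts: dict[str, int] = {}
        for al in observed:
            counts[al] = counts.get(al, 0) + 1
        if len(counts) > 2:
            raise DataError(f"SNP {snp_meta['snp_id'][j]} has >2 alleles")
        if not counts:  # fully missing site
            a1_list.append("A")
            a2_list.append("B")
            continue
        minor, major = _minor_first(counts)
        a1_list.append(minor)
        a2_list.append(major)
        miss = (col == "0").any(axis=1)
        dosage[~miss, j] = (col[~miss] == minor).sum(axis=1)

    snp_meta = snp_meta.drop(columns="cm")
    snp_meta["a1"] = a1_list
    snp_meta["a2"] = a2_list
    return GenotypeMatrix(dosage, snp_meta, np.array(sample_ids, dtype=object))


def read_phenotypes(path) -> pd.DataFrame:
    """Read the phenotype TSV (sex coded 1/2, traits 0/1/NA)."""
    table = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"sample_id": str})
    table["sex"] = table["sex"].map(_SEX_LABEL)
    return validate_sample_table(table)


def read_gene_table(path) -> pd.DataFrame:
    """Read a gene annotation TSV: gene_id, chrom, strand, start, end."""
    genes = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "strand", "start", "end"}
    missing = required - set(genes.columns)
    if missing:
        raise DataError(f"gene table missing columns {sorted(missing)}")
    if (genes["start"] > genes["end"]).any():
        raise DataError("gene start must be <= end")
    if not genes["strand"].isin(["+", "-"]).all():
        raise DataError("strand must be '+' or '-'")
    return genes.reset_index(drop=True)


def write_gene_table(genes: pd.DataFrame, path) -> None:
    genes.to_csv(path, sep="\t", index=False)
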