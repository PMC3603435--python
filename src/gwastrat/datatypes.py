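"""Core in-memory containers shared across the pipeline.

Genotypes live in a samples x SNPs minor-allele dosage matrix (``np.nan``
encodes a missing call); sample phenotypes/covariates live in a pandas
DataFrame with a fixed trait ordering.  Both are deliberately thin wrappers:
all numerical work happens on the underlying numpy/pandas objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Fixed ordering of the six lifetime substance-dependence diagnoses.
TRAITS: tuple[str, ...] = (
    "alcohol",
    "cocaine",
    "marijuana",
    "nicotine",
    "opiates",
    "other",
)

#: The four analysis strata: ancestry group x sex.
STRATA: tuple[tuple[str, str], ...] = (
    ("AFR", "male"),
    ("AFR", "female"),
    ("EUR", "male"),
    ("EUR", "female"),
)

#: Columns every phenotype table must carry, in order.
SAMPLE_COLUMNS: tuple[str, ...] = ("sample_id", "sex", "ancestry", "age") + TRAITS

SNP_META_COLUMNS: tuple[str, ...] = ("snp_id", "chrom", "pos", "a1", "a2")


class DataError(ValueError):
    """Raised when an input container violates its invariants."""


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage matrix counting copies of allele A1.

    Attributes
    ----------
    dosage
        float array of shape ``(n_samples, n_snps)`` with values in
        ``{0, 1, 2}`` or ``np.nan`` for a missing call.
    snp_meta
        One row per SNP with columns ``snp_id, chrom, pos, a1, a2``
        (positions 1-based).
    sample_ids
        One string id per row of ``dosage``.
    """

    dosage: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise DataError("dosage must be 2-dimensional (samples x SNPs)")
        if self.sample_ids is None:
            self.sample_ids = np.array([f"S{i}" for i in range(self.dosage.shape[0])])
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if len(self.sample_ids) != self.dosage.shape[0]:
            raise DataError("sample_ids length does not match dosage rows")
        self.snp_meta = pd.DataFrame(self.snp_meta).reset_index(drop=True)
        missing_cols = set(SNP_META_COLUMNS) - set(self.snp_meta.columns)
        if missing_cols:
            raise DataError(f"snp_meta missing columns {sorted(missing_cols)}")
        if len(self.snp_meta) != self.dosage.shape[1]:
            raise DataError("snp_meta rows do not match dosage columns")
        if self.snp_meta["snp_id"].duplicated().any():
            raise DataError("duplicate SNP ids")
        if (self.snp_meta["pos"] <= 0).any():
            raise DataError("SNP positions must be positive (1-based)")
        if (self.snp_meta["a1"] == self.snp_meta["a2"]).any():
            raise DataError("A1 must differ from A2")
        vals = self.dosage[~np.isnan(self.dosage)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise DataError("dosage values must be in {0,1,2} or NaN")

    # -- shape ----------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    # -- summaries ------------------------------------------------------
    def allele1_freq(self) -> np.ndarray:
        """Frequency of allele A1 per SNP over non-missing genotypes."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP (``min(f, 1-f)``)."""
        f = self.allele1_freq()
        return np.minimum(f, 1.0 - f)

    def sample_call_rate(self) -> np.ndarray:
        """Fraction of non-missing genotypes per sample."""
        return 1.0 - np.isnan(self.dosage).mean(axis=1)

    def genotype_counts(self) -> np.ndarray:
        """(n_snps, 3) counts of dosage 0 / 1 / 2 over non-missing calls."""
        out = np.empty((self.n_snps, 3), dtype=int)
        for k in range(3):
            out[:, k] = np.nansum(self.dosage == k, axis=0)
        return out

    # -- subsetting -----------------------------------------------------
    def take_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.dosage[index, :].copy(),
            self.snp_meta.copy(),
            self.sample_ids[index].copy(),
        )

    def take_snps(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.dosage[:, index].copy(),
            self.snp_meta.iloc[index].reset_index(drop=True),
            self.sample_ids.copy(),
        )

    def snp_index(self, snp_id: str) -> int:
        hits = np.flatnonzero((self.snp_meta["snp_id"] == snp_id).to_numpy())
        if hits.size != 1:
            raise KeyError(snp_id)
        return int(hits[0])


def validate_sample_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a phenotype/covariate table against the expected schema.

    Required columns: ``sample_id, sex, ancestry, age`` plus the six traits
    in the fixed order of :data:`TRAITS`.  Sex is ``male``/``female``,
    ancestry ``AFR``/``EUR``; traits are 0/1 or NaN.
    Returns the table with columns reordered canonically.
    """
    missing = set(SAMPLE_COLUMNS) - set(table.columns)
    if missing:
        raise DataError(f"sample table missing columns {sorted(missing)}")
    if table["sample_id"].duplicated().any():
        raise DataError("duplicate sample ids")
    if not table["sex"].isin(["male", "female"]).all():
        raise DataError("sex must be 'male' or 'female'")
    if not table["ancestry"].isin(["AFR", "EUR"]).all():
        raise DataError("ancestry must be 'AFR' or 'EUR'")
    tvals = table[list(TRAITS)].to_numpy(dtype=float)
    ok = np.isnan(tvals) | np.isin(tvals, (0.0, 1.0))
    if not ok.all():
        raise DataError("trait values must be 0, 1 or missing")
    extra = [c for c in table.columns if c not in SAMPLE_COLUMNS]
    return table[list(SAMPLE_COLUMNS) + extra].reset_index(drop=True)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Case/control x minor/major allele counts.

    ``a``: case minor, ``b``: case major, ``c``: control minor,
    ``d``: control major.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DataError("contingency counts must be non-negative")

    @property
    def total(self) -> float:
        return self.a + self.b + self.c + self.d

    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0

    def swapped_status(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.c, self.d, self.a, self.b)

    def swapped_alleles(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.b, self.a, self.d, self.c)
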