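"""Shared fixtures and independent oracles used across the test suite."""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from gwastrat.datatypes import GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def table3():
    """The exact rare-variant contingency fixture (535 samples, 1 SNP)."""
    from gwastrat.simulate import gen_scenario_table3

    return gen_scenario_table3(seed=1)


def make_genotypes(dosage, chrom="1", pos_start=1000, pos_step=1000):
    """Wrap a raw dosage array in a GenotypeMatrix with generic metadata."""
    dosage = np.asarray(dosage, dtype=float)
    m = dosage.shape[1]
    meta = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(m)],
            "chrom": chrom,
            "pos": pos_start + pos_step * np.arange(m),
            "a1": "G",
            "a2": "A",
        }
    )
    return GenotypeMatrix(dosage, meta)


def hwe_exact_oracle(nAA: int, nAa: int, naa: int) -> Fraction:
    """Exact-rational HWE conditional test by direct integer enumeration.

    Independent of the package implementation: the conditional weight of a
    table with h heterozygotes (given n and the minor allele count) is the
    integer  n! / (hom_rare! h! hom_common!) * 2^h,  and the P value is the
    exact rational sum of weights <= the observed weight over the total.
    """
    n = nAA + nAa + naa
    n_minor = min(2 * nAA + nAa, 2 * naa + nAa)

    def weight(h: int) -> int:
        hr = (n_minor - h) // 2
        hc = n - h - hr
        # multinomial coefficient times 2^h
        return comb(n, h) * comb(n - h, hr) * (2**h)

    hets = range(n_minor % 2, n_minor + 1, 2)
    weights = {h: weight(h) for h in hets}
    w_obs = weights[nAa]
    total = sum(weights.values())
    return Fraction(sum(w for w in weights.values() if w <= w_obs), total)
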