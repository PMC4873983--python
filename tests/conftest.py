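"""Shared fixtures: small deterministic genotype matrices and simulations."""

from __future__ import annotations

import numpy as np
import pytest

import snpkin as sk
from snpkin.genotypes import GenotypeMatrix, SnpSite


def make_matrix(dosage, positions=None, chrom="1", ids=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a plain dosage array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    if positions is None:
        positions = [100 * (k + 1) for k in range(m)]
    if ids is None:
        ids = [f"S{k+1}" for k in range(n)]
    sites = [SnpSite(chrom, int(p)) for p in positions]
    return GenotypeMatrix(ids, sites, dosage)


@pytest.fixture
def toy_matrix() -> GenotypeMatrix:
    """Five individuals, ten sites; for the pair (S1, S2) exactly sites
    1, 3, 7 and 10 carry no minor allele and are excluded."""
    dosage = np.array(
        [
            # sites:  1  2  3  4  5  6  7  8  9 10
            [0, 2, 0, 1, 0, 1, 0, 2, 1, 0],  # S1
            [0, 1, 0, 0, 2, 1, 0, 2, 2, 0],  # S2
            [1, 0, 1, 0, 1, 0, 2, 0, 0, 1],  # S3
            [0, 1, 0, 1, 0, 1, 0, 1, 0, 1],  # S4
            [2, 0, 0, 0, 0, 0, 1, 0, 1, 0],  # S5
        ],
        dtype=np.int8,
    )
    return make_matrix(dosage)


@pytest.fixture(scope="session")
def small_sim():
    """One pedigree unit, 2,000 SNPs: quick end-to-end data."""
    ped = sk.three_generation_template(1)
    g, truth, _ = sk.simulate_pedigree(ped, m=2_000, seed=7)
    return g, truth, ped


@pytest.fixture(scope="session")
def study_sim():
    """Three pedigree units (60 individuals), 10,000 SNPs on one 59 Mb
    chromosome with a uniform 1 cM/Mb map: the reference study design."""
    ped = sk.three_generation_template(3)
    g, truth, _ = sk.simulate_pedigree(ped, m=10_000, seed=11)
    return g, truth, ped


def cross_pedigree_founder_pairs(ped: sk.Pedigree) -> list[tuple[str, str]]:
    """All founder pairs whose members belong to different pedigree units."""
    from itertools import combinations

    unit = lambda s: s.split("_")[0]  # noqa: E731
    return [
        (a, b)
        for a, b in combinations(ped.founders, 2)
        if unit(a) != unit(b)
    ]
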