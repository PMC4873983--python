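"""Spatial-distance feature vectors for individual pairs.

For one pair of individuals, sites where both are homozygous major are
dropped; at each remaining site where an individual carries a minor
allele, the feature is the physical gap (in bp) to that individual's
nearest upstream minor-allele site among the retained sites, doubled when
both endpoint genotypes are homozygous minor.  An artificial start with
genotype ``aa`` is anchored just before the first retained site of each
chromosome so the genotype at the first real minor-allele site remains
distinguishable; no gap ever spans a chromosome boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import GenotypeMatrix

DEFAULT_EPSILON = 1e-16

__all__ = [
    "DEFAULT_EPSILON",
    "PairFeatureVectors",
    "NoInformativeSitesError",
    "filter_pair_sites",
    "build_features",
]


class NoInformativeSitesError(ValueError):
    """Raised when a pair shares no site with a minor allele."""


@dataclass
class PairFeatureVectors:
    """Aligned distance-feature vectors for one individual pair.

    ``positions`` includes the artificial start prepended to every
    chromosome block (feature 0 for both individuals there).
    """

    pair: tuple[str, str]
    positions: np.ndarray
    v1: np.ndarray
    v2: np.ndarray
    n_starts: int = 1

    def __post_init__(self):
        if not (len(self.positions) == len(self.v1) == len(self.v2)):
            raise ValueError("positions, v1 and v2 must have equal length")

    @property
    def n_sites(self) -> int:
        """Number of retained genuine sites (artificial starts excluded)."""
        return len(self.positions) - self.n_starts


def filter_pair_sites(g: GenotypeMatrix, i: str, j: str) -> np.ndarray:
    """Indices of sites where at least one of ``i``, ``j`` carries a minor
    allele, in position order.  Sites with a missing call in either
    individual are dropped for this pair."""
    di, dj = g.row(i), g.row(j)
    called = (di >= 0) & (dj >= 0)
    return np.flatnonzero(called & ((di > 0) | (dj > 0)))


def _individual_features(pos: np.ndarray, dos: np.ndarray, eps: float) -> np.ndarray:
    """Distance features for one individual over one chromosome block.

    ``pos`` are the retained positions (float), ``dos`` the individual's
    dosages there.  The upstream anchor is the artificial start at
    (first retained position - eps) with genotype aa; the gap from it is
    computed as (pos - first_retained) + eps so it is exact at bp scale.
    """
    f = np.zeros(pos.size)
    idx = np.flatnonzero(dos > 0)
    if idx.size == 0:
        return f
    p = pos[idx]
    gaps = np.empty(idx.size)
    gaps[0] = (p[0] - pos[0]) + eps
    if idx.size > 1:
        gaps[1:] = np.diff(p)
    prev_aa = np.empty(idx.size, dtype=bool)
    prev_aa[0] = True  # artificial start carries genotype aa
    if idx.size > 1:
        prev_aa[1:] = dos[idx[:-1]] == 2
    both_aa = prev_aa & (dos[idx] == 2)
    f[idx] = np.where(both_aa, 2.0 * gaps, gaps)
    return f


def build_features(
    g: GenotypeMatrix, i: str, j: str, *, epsilon: float = DEFAULT_EPSILON
) -> PairFeatureVectors:
    """Build the pair's two aligned distance-feature vectors.

    Raises :class:`NoInformativeSitesError` when the pair retains no site.
    """
    retained = filter_pair_sites(g, i, j)
    if retained.size == 0:
        raise NoInformativeSitesError(f"no informative sites for pair ({i}, {j})")

    di = g.row(i)[retained].astype(np.int64)
    dj = g.row(j)[retained].astype(np.int64)
    pos = g.positions[retained].astype(float)
    chrom = g.chromosomes[retained]

    positions_out: list[np.ndarray] = []
    v1_out: list[np.ndarray] = []
    v2_out: list[np.ndarray] = []
    n_starts = 0
    # fresh artificial start per chromosome: no gap spans two chromosomes
    boundaries = np.flatnonzero(np.r_[True, chrom[1:] != chrom[:-1]])
    for b, e in zip(boundaries, np.r_[boundaries[1:], chrom.size]):
        p = pos[b:e]
        positions_out.append(np.r_[p[0] - epsilon, p])
        v1_out.append(np.r_[0.0, _individual_features(p, di[b:e], epsilon)])
        v2_out.append(np.r_[0.0, _individual_features(p, dj[b:e], epsilon)])
        n_starts += 1

    return PairFeatureVectors(
        pair=(i, j),
        positions=np.concatenate(positions_out),
        v1=np.concatenate(v1_out),
        v2=np.concatenate(v2_out),
        n_starts=n_starts,
    )


def dump_features(fv: PairFeatureVectors, path) -> None:
    """Write a pair's feature vectors as tab-separated text (debug aid)."""
    import pandas as pd

    pd.DataFrame(
        {"position": fv.positions, fv.pair[0]: fv.v1, fv.pair[1]: fv.v2}
    ).to_csv(path, sep="\t", index=False)
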