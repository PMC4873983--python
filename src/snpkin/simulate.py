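"""Pedigree genotype simulation with recombination.

Provides non-inbred three-generation pedigree templates, simulated
unrelated founders (per-site MAF drawn uniformly from [0.05, 0.5],
linkage equilibrium), Poisson-crossover meiosis under a genetic map
(uniform 1 cM/Mb by default), gene-dropping down the pedigree, and the
exact recursive kinship coefficient, so the whole estimator can be
validated end-to-end without external data.

All randomness flows from a single integer seed; identical seeds give
identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, SnpSite

__all__ = [
    "PedigreeMember",
    "Pedigree",
    "GeneticMap",
    "three_generation_template",
    "pedigree_kinship",
    "relationship_table",
    "simulate_founders",
    "meiosis",
    "simulate_pedigree",
    "write_pedigree",
]


@dataclass(frozen=True)
class PedigreeMember:
    id: str
    father: str | None
    mother: str | None
    generation: int

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


@dataclass
class Pedigree:
    """Ordered pedigree; parents always precede their children."""

    members: list[PedigreeMember]
    _by_id: dict[str, PedigreeMember] = field(init=False, repr=False)

    def __post_init__(self):
        self._by_id = {}
        for m in self.members:
            if m.id in self._by_id:
                raise ValueError(f"duplicate pedigree id {m.id!r}")
            if (m.father is None) != (m.mother is None):
                raise ValueError(f"{m.id!r}: both parents or neither")
            for parent in (m.father, m.mother):
                if parent is not None:
                    if parent not in self._by_id:
                        raise ValueError(
                            f"{m.id!r}: parent {parent!r} must precede the child"
                        )
                    if self._by_id[parent].generation >= m.generation:
                        raise ValueError(
                            f"{m.id!r}: parent {parent!r} must belong to an "
                            "earlier generation"
                        )
            self._by_id[m.id] = m

    def __getitem__(self, mid: str) -> PedigreeMember:
        try:
            return self._by_id[mid]
        except KeyError:
            raise KeyError(f"unknown pedigree member {mid!r}") from None

    def __contains__(self, mid: str) -> bool:
        return mid in self._by_id

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.members]

    @property
    def founders(self) -> list[str]:
        return [m.id for m in self.members if m.is_founder]


def three_generation_template(n_pedigrees: int = 1, prefix: str = "P") -> Pedigree:
    """Default non-inbred three-generation pedigree template.

    Each 20-member unit has two grandparental couples (founders), five
    second-generation children (a sibship of three and a sibship of
    two), four married-in founder spouses, and seven grandchildren in
    four nuclear families.  The unit contains parent-offspring (24),
    full-sibling (8), second-degree (26: grandparent-grandchild and
    avuncular), third-degree (7: first-cousin) and unrelated pairs —
    roughly the per-pedigree class profile of a 150-individual,
    7-pedigree study — and distinct units are mutually unrelated.
    """
    members: list[PedigreeMember] = []
    for k in range(1, n_pedigrees + 1):
        t = f"{prefix}{k}_"
        f = lambda mid: PedigreeMember(t + mid, None, None, 0)  # noqa: E731
        c = lambda mid, fa, mo, gen: PedigreeMember(  # noqa: E731
            t + mid, t + fa, t + mo, gen
        )
        members += [f("gpA1"), f("gpA2"), f("gpB1"), f("gpB2"),
                    f("m1"), f("m2"), f("m3"), f("m4")]
        members += [
            # sibship of three from couple A, sibship of two from couple B
            c("p1", "gpA1", "gpA2", 1),
            c("p2", "gpA1", "gpA2", 1),
            c("p3", "gpA1", "gpA2", 1),
            c("q1", "gpB1", "gpB2", 1),
            c("q2", "gpB1", "gpB2", 1),
            # grandchildren: p1 x m1 (three), p2 x m2 (two),
            # q1 x m3 (one), q2 x m4 (one); p3 is unmarried
            c("c1", "p1", "m1", 2),
            c("c2", "p1", "m1", 2),
            c("c3", "p1", "m1", 2),
            c("c4", "p2", "m2", 2),
            c("c5", "p2", "m2", 2),
            c("c6", "q1", "m3", 2),
            c("c7", "q2", "m4", 2),
        ]
    return Pedigree(members)


def pedigree_kinship(ped: Pedigree, i: str, j: str) -> float:
    """Theoretical kinship coefficient by the standard recursion.

    phi(i, i) = (1 + phi(father_i, mother_i)) / 2; for distinct
    individuals the recursion descends through the parents of the member
    in the later generation (founders are mutually unrelated), which
    guarantees the descent never passes through an ancestor of the other
    individual.
    """
    cache: dict[tuple[str, str], float] = {}

    def phi(a: str, b: str) -> float:
        ma, mb = ped[a], ped[b]
        if a == b:
            if ma.is_founder:
                return 0.5
            return 0.5 * (1.0 + phi(ma.father, ma.mother))
        key = (a, b) if a < b else (b, a)
        if key in cache:
            return cache[key]
        # recurse on the later-generation member
        if (ma.generation, a) < ((mb.generation, b)):
            ma, mb, a, b = mb, ma, b, a
        if ma.is_founder:
            val = 0.0
        else:
            val = 0.5 * (phi(ma.father, b) + phi(ma.mother, b))
        cache[key] = val
        return val

    return phi(i, j)


def _classify(ped: Pedigree, i: str, j: str, phi: float) -> str:
    mi, mj = ped[i], ped[j]
    if j in (mi.father, mi.mother) or i in (mj.father, mj.mother):
        return "PO"
    if (
        not mi.is_founder
        and {mi.father, mi.mother} == {mj.father, mj.mother}
    ):
        return "FS"
    for rel, val in (("2ND", 0.125), ("3RD", 0.0625), ("UN", 0.0)):
        if np.isclose(phi, val):
            return rel
    return "OTHER"


def relationship_table(ped: Pedigree) -> pd.DataFrame:
    """All pairs with relationship label and theoretical kinship.

    Columns: id1, id2, relationship (PO/FS/2ND/3RD/UN/OTHER), phi_true.
    """
    rows = []
    for i, j in combinations(ped.ids, 2):
        phi = pedigree_kinship(ped, i, j)
        rows.append((i, j, _classify(ped, i, j, phi), phi))
    return pd.DataFrame(rows, columns=["id1", "id2", "relationship", "phi_true"])


def write_pedigree(ped: Pedigree, path) -> None:
    """Write a PED-like four-column file: id, father, mother, generation."""
    with open(path, "w") as fh:
        fh.write("id\tfather\tmother\tgeneration\n")
        for m in ped.members:
            fh.write(f"{m.id}\t{m.father or '0'}\t{m.mother or '0'}\t{m.generation}\n")


# ---------------------------------------------------------------------------
# recombination


@dataclass
class GeneticMap:
    """Recombination map: uniform rate or piecewise-constant segments.

    ``rate_cm_per_mb`` gives a uniform rate; alternatively ``segments``
    is a list of (start bp, rate cM/Mb) pairs, each rate applying from
    its start to the next segment's start (the last one to the
    chromosome end).
    """

    rate_cm_per_mb: float = 1.0
    segments: list[tuple[int, float]] | None = None

    def __post_init__(self):
        if self.segments is not None:
            starts = [s for s, _ in self.segments]
            if sorted(starts) != starts:
                raise ValueError("segment positions must increase")
            if any(r < 0 for _, r in self.segments):
                raise ValueError("recombination rates must be non-negative")
        elif self.rate_cm_per_mb < 0:
            raise ValueError("recombination rate must be non-negative")

    def _cumulative(self, length_bp: float):
        """Breakpoints (bp) and cumulative genetic position (Morgans)."""
        if self.segments is None:
            bp = np.array([0.0, length_bp])
            morgans = np.array([0.0, length_bp * self.rate_cm_per_mb / 1e8])
            return bp, morgans
        bp = np.array([s for s, _ in self.segments] + [length_bp], dtype=float)
        rates = np.array([r for _, r in self.segments], dtype=float)
        seg_m = np.diff(bp) * rates / 1e8
        return bp, np.r_[0.0, np.cumsum(seg_m)]

    def genetic_length(self, length_bp: float) -> float:
        """Total genetic length of a chromosome in Morgans."""
        return float(self._cumulative(length_bp)[1][-1])

    def crossover_positions(self, length_bp: float, rng: np.random.Generator):
        """Crossover bp positions: Poisson count, placed by the map."""
        bp, morgans = self._cumulative(length_bp)
        total = morgans[-1]
        n = rng.poisson(total) if total > 0 else 0
        if n == 0:
            return np.empty(0)
        gpos = np.sort(rng.uniform(0.0, total, n))
        return np.interp(gpos, morgans, bp)


def meiosis(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    gmap: GeneticMap,
    rng: np.random.Generator,
    *,
    length_bp: float | None = None,
) -> np.ndarray:
    """One gamete from a (2, M) parental haplotype pair.

    The crossover count is Poisson with mean equal to the map's genetic
    length; the starting haplotype is a fair coin; the source haplotype
    alternates at each crossover.
    """
    haplotypes = np.asarray(haplotypes)
    if haplotypes.ndim != 2 or haplotypes.shape[0] != 2:
        raise ValueError("haplotypes must have shape (2, M)")
    length = float(length_bp if length_bp is not None else positions[-1])
    cross = gmap.crossover_positions(length, rng)
    start = rng.integers(0, 2)
    n_before = np.searchsorted(cross, positions)
    source = (start + n_before) % 2
    return haplotypes[source, np.arange(positions.size)]


# ---------------------------------------------------------------------------
# founders and gene dropping


def simulate_founders(
    n: int,
    m: int,
    *,
    maf_law: tuple = ("uniform", 0.05, 0.5),
    seed: int = 0,
    chromosome: str = "1",
    length_bp: int = 59_000_000,
    ids: list[str] | None = None,
):
    """Simulate unrelated founder haplotypes in linkage equilibrium.

    Per-site MAF is drawn from ``maf_law`` — ("uniform", lo, hi) or
    ("fixed", value) — and haplotype alleles independently per site at
    that frequency.  Site positions are drawn uniformly without
    replacement from [1, length_bp] and sorted.

    Returns (haplotypes, genotype_matrix, sites): haplotypes maps id ->
    (2, m) binary minor-allele indicator array.
    """
    if n < 1 or m < 1:
        raise ValueError("need n >= 1 founders and m >= 1 sites")
    if m > length_bp:
        raise ValueError("more sites than available positions")
    rng = np.random.default_rng(seed)
    kind = maf_law[0]
    if kind == "uniform":
        maf = rng.uniform(maf_law[1], maf_law[2], m)
    elif kind == "fixed":
        maf = np.full(m, float(maf_law[1]))
    else:
        raise ValueError(f"unknown MAF law {maf_law!r}")
    positions = np.sort(rng.choice(length_bp, size=m, replace=False)) + 1
    sites = [
        SnpSite(chromosome, int(p), maf=float(f))
        for p, f in zip(positions, maf)
    ]
    if ids is None:
        ids = [f"F{k+1}" for k in range(n)]
    haplotypes = {
        s: (rng.random((2, m)) < maf).astype(np.int8) for s in ids
    }
    dosage = np.vstack([haplotypes[s].sum(axis=0) for s in ids])
    return haplotypes, GenotypeMatrix(list(ids), sites, dosage), sites


def simulate_pedigree(
    pedigree: Pedigree,
    *,
    m: int = 10_000,
    maf_law: tuple = ("uniform", 0.05, 0.5),
    gmap: GeneticMap | None = None,
    seed: int = 0,
    chromosome: str = "1",
    length_bp: int = 59_000_000,
    founder_haplotypes: dict[str, np.ndarray] | None = None,
    sites: list[SnpSite] | None = None,
):
    """Gene-drop genotypes down a pedigree on one synthetic chromosome.

    Founder haplotypes are simulated by default; alternatively pass
    ``founder_haplotypes`` (id -> (2, M) minor-allele indicator array,
    e.g. phased haplotypes loaded from a VCF) together with ``sites``.
    Each transmission recombines the parental chromosomes under ``gmap``
    (uniform 1 cM/Mb by default).

    Returns (genotype_matrix, truth, pedigree): ``truth`` is the
    all-pairs relationship table of :func:`relationship_table`.
    """
    gmap = gmap or GeneticMap()
    rng = np.random.default_rng(seed)
    founders = pedigree.founders
    if founder_haplotypes is None:
        if sites is not None:
            raise ValueError("sites requires founder_haplotypes")
        haps, _, sites = simulate_founders(
            len(founders), m, maf_law=maf_law,
            seed=int(rng.integers(2**31)), chromosome=chromosome,
            length_bp=length_bp, ids=founders,
        )
    else:
        if sites is None:
            raise ValueError("founder_haplotypes requires sites")
        missing = [f for f in founders if f not in founder_haplotypes]
        if missing:
            raise ValueError(
                f"template requires founders absent from the supplied "
                f"haplotypes: {missing}"
            )
        haps = {f: np.asarray(founder_haplotypes[f]) for f in founders}
    positions = np.array([s.position for s in sites], dtype=float)
    length = float(max(length_bp, positions[-1]))

    for member in pedigree.members:
        if member.is_founder:
            continue
        pat = meiosis(haps[member.father], positions, gmap, rng,
                      length_bp=length)
        mat = meiosis(haps[member.mother], positions, gmap, rng,
                      length_bp=length)
        haps[member.id] = np.vstack([pat, mat])

    ids = pedigree.ids
    dosage = np.vstack([haps[s].sum(axis=0) for s in ids])
    g = GenotypeMatrix(ids, sites, dosage)
    return g, relationship_table(pedigree), pedigree
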