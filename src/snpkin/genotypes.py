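"""Genotype containers and I/O.

Genotypes are held as a positioned minor-allele dosage matrix: rows are
individuals, columns are biallelic SNP sites ordered by (chromosome,
position), entries count copies of the *minor* allele (0, 1, 2) with -1
marking a missing call.  The minor allele at a site is always the less
frequent allele in the loaded cohort; when loading VCF the dosages are
recoded accordingly, so the per-site minor-allele frequency never exceeds
0.5 (a frequency tie is broken toward the ALT allele).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

__all__ = [
    "MISSING",
    "SnpSite",
    "GenotypeMatrix",
    "GenotypeError",
    "read_vcf",
    "read_matrix",
    "write_matrix",
    "concatenate",
]


class GenotypeError(ValueError):
    """Raised for malformed or inconsistent genotype input."""


def _chrom_key(chrom: str):
    """Sort key placing numeric chromosome names in natural order."""
    s = str(chrom)
    s2 = s[3:] if s.lower().startswith("chr") else s
    try:
        return (0, int(s2), "")
    except ValueError:
        return (1, 0, s2)


@dataclass(frozen=True)
class SnpSite:
    """A biallelic SNP site with 1-based physical coordinates."""

    chromosome: str
    position: int
    major_allele: str = "A"
    minor_allele: str = "a"
    maf: float = float("nan")

    def __post_init__(self):
        if self.position < 1:
            raise GenotypeError(
                f"site {self.chromosome}:{self.position}: position must be >= 1"
            )

    @property
    def label(self) -> str:
        return f"{self.chromosome}:{self.position}"


@dataclass
class GenotypeMatrix:
    """N individuals x M positioned sites of minor-allele dosages.

    ``dosage`` is an ``int8`` array; entries are 0/1/2 or :data:`MISSING`.
    Sites are kept sorted by (chromosome, position) with strictly
    increasing positions within each chromosome.
    """

    individuals: list[str]
    sites: list[SnpSite]
    dosage: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        self.individuals = list(self.individuals)
        self.sites = list(self.sites)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n, m = len(self.individuals), len(self.sites)
        if self.dosage.shape != (n, m):
            raise GenotypeError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{n} individuals x {m} sites"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise GenotypeError(
                f"invalid dosage {self.dosage[r, c]} for individual "
                f"{self.individuals[r]!r} at site {self.sites[c].label}"
            )
        if len(set(self.individuals)) != n:
            raise GenotypeError("duplicate individual identifiers")
        self._check_site_order()
        self._index = {s: i for i, s in enumerate(self.individuals)}

    def _check_site_order(self):
        seen: dict[str, int] = {}
        prev_key = None
        for s in self.sites:
            key = _chrom_key(s.chromosome)
            if prev_key is not None and key < prev_key:
                raise GenotypeError("sites are not in chromosome order")
            if key != prev_key:
                if s.chromosome in seen:
                    raise GenotypeError(
                        f"chromosome {s.chromosome} appears in two blocks"
                    )
                seen[s.chromosome] = 0
            else:
                if s.position <= seen[s.chromosome]:
                    raise GenotypeError(
                        f"positions not strictly increasing on chromosome "
                        f"{s.chromosome} at {s.position}"
                    )
            seen[s.chromosome] = s.position
            prev_key = key

    # -- convenience accessors -------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.sites], dtype=np.int64)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.array([s.chromosome for s in self.sites])

    def row(self, individual: str) -> np.ndarray:
        return self.dosage[self.index_of(individual)]

    def index_of(self, individual: str) -> int:
        try:
            return self._index[individual]
        except KeyError:
            raise GenotypeError(f"unknown individual {individual!r}") from None

    def subset(self, individuals: list[str]) -> "GenotypeMatrix":
        rows = [self.index_of(s) for s in individuals]
        return GenotypeMatrix(list(individuals), self.sites, self.dosage[rows])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosage,
            index=pd.Index(self.individuals, name="id"),
            columns=[s.label for s in self.sites],
        )


def _sorted_site_order(sites: list[SnpSite]) -> np.ndarray:
    keys = [(_chrom_key(s.chromosome), s.position) for s in sites]
    return np.array(sorted(range(len(sites)), key=keys.__getitem__), dtype=int)


def read_vcf(path, sample_subset: list[str] | None = None) -> GenotypeMatrix:
    """Load biallelic SNPs from a VCF into a minor-allele dosage matrix.

    Dosages are recoded relative to the minor allele as observed in the
    loaded samples; multi-allelic and indel records are skipped and
    counted.  Phase is discarded.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise GenotypeError(f"cannot read VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    if sample_subset is not None:
        for s in sample_subset:
            if s not in samples:
                raise GenotypeError(f"sample {s!r} not present in {path}")
        keep = np.array([samples.index(s) for s in sample_subset])
        samples = list(sample_subset)
    else:
        keep = np.arange(len(samples))

    sites: list[SnpSite] = []
    columns: list[np.ndarray] = []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            skipped += 1
            continue
        # gts012=True: 0/1/2 = ALT dosage, 3 = unknown
        alt = np.asarray(var.gt_types)[keep].astype(np.int8)
        miss = alt == 3
        called = alt[~miss]
        if called.size == 0:
            skipped += 1
            continue
        alt_freq = called.sum() / (2.0 * called.size)
        if alt_freq <= 0.5:  # tie broken toward ALT as minor
            dos, major, minor, maf = alt, var.REF, var.ALT[0], alt_freq
        else:
            dos, major, minor, maf = 2 - alt, var.ALT[0], var.REF, 1 - alt_freq
        dos = dos.copy()
        dos[miss] = MISSING
        sites.append(SnpSite(str(var.CHROM), int(var.POS), major, minor, maf))
        columns.append(dos)

    if skipped:
        logger.warning("skipped %d non-biallelic-SNP records in %s", skipped, path)
    if not sites:
        raise GenotypeError(f"no biallelic SNP sites loaded from {path}")

    dosage = np.column_stack(columns)
    order = _sorted_site_order(sites)
    g = GenotypeMatrix(samples, [sites[i] for i in order], dosage[:, order])
    logger.info(
        "loaded %d individuals, %d sites, skipped %d records",
        g.n_individuals, g.n_sites, skipped,
    )
    return g


def read_matrix(path) -> GenotypeMatrix:
    """Read the tab-separated dosage dialect.

    Header row holds site labels ``chrom:pos``; the first column is the
    sample id; entries are 0/1/2 (minor-allele counts, taken as-is) or NA.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise GenotypeError(f"{path}: no site columns found")
    sites = []
    for label in df.columns:
        try:
            chrom, pos = str(label).rsplit(":", 1)
            sites.append(SnpSite(chrom, int(pos)))
        except (ValueError, GenotypeError) as exc:
            raise GenotypeError(f"{path}: bad site label {label!r}: {exc}") from exc

    vals = df.to_numpy()
    dosage = np.full(vals.shape, MISSING, dtype=np.int8)
    ok = {"0": 0, "1": 1, "2": 2, "NA": MISSING, "nan": MISSING}
    for (r, c), v in np.ndenumerate(vals):
        v = str(v)
        if v not in ok:
            raise GenotypeError(
                f"{path}: invalid entry {v!r} at row {df.index[r]!r}, "
                f"column {df.columns[c]!r} (expected 0/1/2/NA)"
            )
        dosage[r, c] = ok[v]

    pairs = {(s.chromosome, s.position) for s in sites}
    if len(pairs) != len(sites):
        raise GenotypeError(f"{path}: duplicated chromosome:position column")
    order = _sorted_site_order(sites)
    g = GenotypeMatrix(
        [str(i) for i in df.index], [sites[i] for i in order], dosage[:, order]
    )
    logger.info("loaded %d individuals, %d sites", g.n_individuals, g.n_sites)
    return g


def write_matrix(g: GenotypeMatrix, path) -> None:
    """Write the tab-separated dosage dialect read by :func:`read_matrix`."""
    df = g.to_dataframe().astype(object)
    df[g.dosage == MISSING] = "NA"
    df.to_csv(path, sep="\t")


def concatenate(matrices: list[GenotypeMatrix]) -> GenotypeMatrix:
    """Concatenate per-chromosome matrices in ascending chromosome order.

    All matrices must carry identical individual lists and disjoint
    chromosome sets.
    """
    if not matrices:
        raise GenotypeError("nothing to concatenate")
    if len(matrices) == 1:
        return matrices[0]
    first = matrices[0]
    for m in matrices[1:]:
        if m.individuals != first.individuals:
            raise GenotypeError("individual lists differ between matrices")
    chroms = [set(m.chromosomes) for m in matrices]
    if len(set().union(*chroms)) != sum(len(c) for c in chroms):
        raise GenotypeError("matrices share a chromosome")
    order = sorted(range(len(matrices)),
                   key=lambda i: min(_chrom_key(c) for c in chroms[i]))
    sites = [s for i in order for s in matrices[i].sites]
    dosage = np.concatenate([matrices[i].dosage for i in order], axis=1)
    return GenotypeMatrix(list(first.individuals), sites, dosage)
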