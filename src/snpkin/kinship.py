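"""Kinship coefficients from Minkowski dissimilarity of feature vectors.

The dissimilarity between two individuals is the Minkowski distance
``(sum |x_i - y_i|^p)^(1/p)`` of their spatial-distance feature vectors;
orders 0 < p < 1 are accepted although the triangle inequality then fails
(the distance is a semi-metric).  The estimated kinship coefficient is

    phi_hat = (1 - d / d_t) / 2

where ``d_t`` is a baseline approximating the expected dissimilarity of
two unrelated individuals — here the mean distance over declared-unrelated
training pairs.  Identical genotype vectors give d = 0 and phi_hat = 0.5;
a pair more dissimilar than the baseline gets a negative estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .features import DEFAULT_EPSILON, build_features
from .genotypes import GenotypeMatrix

__all__ = [
    "KinshipModel",
    "KinshipEstimate",
    "minkowski",
    "log_minkowski",
    "estimate_d_t",
    "kinship_pair",
    "kinship_matrix",
    "write_model",
    "read_model",
]


def log_minkowski(x: np.ndarray, y: np.ndarray, p: float) -> float:
    """log of the Minkowski distance of order ``p`` (``-inf`` if x == y).

    Computed as ``logsumexp(p * log|x - y|) / p`` over the non-zero
    coordinate differences, which stays finite for small fractional
    orders where the plain power sum would overflow.  Zero differences
    contribute nothing for p > 0 and are excluded by the same continuity
    convention when a (diagnostic) negative order is requested.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if p == 0:
        raise ValueError("Minkowski order p must be non-zero")
    diff = np.abs(x - y)
    nz = diff[diff > 0]
    if nz.size == 0:
        return -np.inf
    return float(logsumexp(p * np.log(nz)) / p)


def minkowski(x: np.ndarray, y: np.ndarray, p: float) -> float:
    """Minkowski distance of order ``p > 0`` between equal-length vectors."""
    if p <= 0:
        raise ValueError(f"Minkowski order p must be > 0, got {p}")
    ld = log_minkowski(x, y, p)
    return 0.0 if ld == -np.inf else float(np.exp(ld))


@dataclass
class KinshipModel:
    """Fitted model: Minkowski order ``p`` and unrelated baseline ``d_t``."""

    p: float
    d_t: float
    epsilon: float = DEFAULT_EPSILON
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0 < self.p <= 1:
            raise ValueError(f"order p must lie in (0, 1], got {self.p}")
        if not self.d_t > 0:
            raise ValueError(f"baseline d_t must be positive, got {self.d_t}")


@dataclass(frozen=True)
class KinshipEstimate:
    """Kinship estimate for one pair; ``phi_hat = (1 - d/d_t)/2``."""

    pair: tuple[str, str]
    phi_hat: float
    d: float
    n_sites: int


def estimate_d_t(
    g: GenotypeMatrix,
    unrelated_pairs: list[tuple[str, str]],
    p: float,
    *,
    epsilon: float = DEFAULT_EPSILON,
) -> float:
    """Mean Minkowski distance at order ``p`` over declared-unrelated pairs.

    By construction the average phi_hat of these pairs is exactly 0.
    """
    if not unrelated_pairs:
        raise ValueError(
            "no unrelated pairs supplied: d_t needs at least one pair of "
            "individuals declared unrelated"
        )
    ds = []
    for i, j in unrelated_pairs:
        fv = build_features(g, i, j, epsilon=epsilon)
        ds.append(minkowski(fv.v1, fv.v2, p))
    return float(np.mean(ds))


def kinship_pair(
    g: GenotypeMatrix, i: str, j: str, model: KinshipModel
) -> KinshipEstimate:
    """Estimate the kinship coefficient of one pair under a fitted model.

    Self-pairs short-circuit to phi_hat = 0.5 (d = 0) without computing
    features; the result is identical and exact.
    """
    if i == j:
        g.index_of(i)
        return KinshipEstimate((i, j), 0.5, 0.0, g.n_sites)
    fv = build_features(g, i, j, epsilon=model.epsilon)
    d = minkowski(fv.v1, fv.v2, model.p)
    phi = (1.0 - d / model.d_t) / 2.0
    return KinshipEstimate((i, j), phi, d, fv.n_sites)


def kinship_matrix(
    g: GenotypeMatrix,
    model: KinshipModel,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Kinship estimates for all N(N-1)/2 pairs (or a requested subset).

    Returns a DataFrame with columns id1, id2, n_sites, distance, phi_hat;
    every requested pair receives a numeric estimate.
    """
    if pairs is None:
        pairs = list(combinations(g.individuals, 2))
    rows = []
    for i, j in pairs:
        est = kinship_pair(g, i, j, model)
        rows.append((i, j, est.n_sites, est.d, est.phi_hat))
    return pd.DataFrame(
        rows, columns=["id1", "id2", "n_sites", "distance", "phi_hat"]
    )


def write_model(model: KinshipModel, path) -> None:
    """Serialize a fitted model as a small key-value text document."""
    with open(path, "w") as fh:
        fh.write(f"p\t{model.p!r}\n")
        fh.write(f"d_t\t{model.d_t!r}\n")
        fh.write(f"epsilon\t{model.epsilon!r}\n")
        for k, v in model.provenance.items():
            fh.write(f"{k}\t{v}\n")


def read_model(path) -> KinshipModel:
    fields: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                k, _, v = line.rstrip("\n").partition("\t")
                fields[k] = v
    try:
        p = float(fields.pop("p"))
        d_t = float(fields.pop("d_t"))
    except KeyError as exc:
        raise ValueError(f"model file {path} lacks field {exc}") from exc
    eps = float(fields.pop("epsilon", DEFAULT_EPSILON))
    return KinshipModel(p=p, d_t=d_t, epsilon=eps, provenance=fields)
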