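"""Stratified kinship estimation for heterogeneous cohorts.

Hidden subgroups with divergent allele frequencies bias a single global
calibration, so individuals are first clustered by k-means on their raw
minor-allele dosage rows under the 1 - Pearson-correlation dissimilarity
(ten random restarts per k, minimum point-to-centroid inertia kept).
A separate order parameter and baseline are then fitted within every
cluster and for every cluster pair (pooling the two clusters' training
pairs), and the per-block estimates are merged into one table covering
every pair exactly once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .fit import LabeledPair, fit_p
from .genotypes import GenotypeMatrix
from .kinship import kinship_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterAssignment",
    "cluster_individuals",
    "select_k",
    "stratified_kinship",
    "write_assignment",
]


@dataclass
class ClusterAssignment:
    """k-means result: individual -> cluster (1..k) plus diagnostics."""

    k: int
    labels: dict[str, int]
    inertia: float
    restarts_used: int
    flagged: list[str] = field(default_factory=list)
    per_k: dict[int, "ClusterAssignment"] | None = None

    def members(self, cluster: int) -> list[str]:
        return [s for s, c in self.labels.items() if c == cluster]


def _corr_dissimilarity(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between every row of X and every row of C.

    Zero-variance rows have undefined correlation; their entries come out
    NaN and are resolved by the caller's fallback.
    """
    Xc = X - X.mean(axis=1, keepdims=True)
    Cc = C - C.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(Xc, axis=1)
    cn = np.linalg.norm(Cc, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (Xc @ Cc.T) / np.outer(xn, cn)
    return 1.0 - corr


def _kmeans_once(X: np.ndarray, k: int, rng: np.random.Generator, maxiter: int):
    n = X.shape[0]
    centroids = X[rng.choice(n, size=k, replace=False)].astype(float)
    labels = np.full(n, -1)
    flagged = np.zeros(n, dtype=bool)
    for _ in range(maxiter):
        D = _corr_dissimilarity(X, centroids)
        bad = np.isnan(D).all(axis=1)
        if bad.any():
            # constant dosage row: correlation undefined; fall back to
            # Euclidean nearest centroid and flag the individual
            E = ((X[bad, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
            D[bad] = E
            flagged |= bad
        D = np.nan_to_num(D, nan=2.0)  # centroid-side degeneracy: max dissim
        new_labels = D.argmin(axis=1)
        for c in range(k):
            if not (new_labels == c).any():  # re-seed empty cluster
                new_labels[rng.integers(0, n)] = c
        if (new_labels == labels).all():
            break
        labels = new_labels
        for c in range(k):
            centroids[c] = X[labels == c].mean(axis=0)
    D = _corr_dissimilarity(X, centroids)
    if np.isnan(D).any():
        E = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        D = np.where(np.isnan(D), E, D)
    inertia = float(D[np.arange(n), labels].sum())
    return labels, inertia, flagged


def cluster_individuals(
    g: GenotypeMatrix,
    k: int,
    restarts: int = 10,
    seed: int = 0,
    *,
    maxiter: int = 100,
) -> ClusterAssignment:
    """k-means under 1 - Pearson dissimilarity on dosage rows.

    Centroids are arithmetic means of member rows; the best of
    ``restarts`` random initializations (minimum inertia) is returned.
    Deterministic given ``seed``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if g.n_individuals < k:
        raise ValueError(f"cannot form {k} clusters from {g.n_individuals} individuals")
    X = g.dosage.astype(float)
    X[g.dosage < 0] = np.nan
    # missing dosages replaced by the site mean so correlation is defined
    if np.isnan(X).any():
        means = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), means, X)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, restarts)):
        labels, inertia, flagged = _kmeans_once(X, k, rng, maxiter)
        if best is None or inertia < best[1]:
            best = (labels, inertia, flagged)
    labels, inertia, flagged = best
    return ClusterAssignment(
        k=k,
        labels={s: int(c) + 1 for s, c in zip(g.individuals, labels)},
        inertia=inertia,
        restarts_used=max(1, restarts),
        flagged=[s for s, f in zip(g.individuals, flagged) if f],
    )


def select_k(
    g: GenotypeMatrix,
    k_range=range(1, 6),
    restarts: int = 10,
    seed: int = 0,
    *,
    elbow_threshold: float = 0.2,
    force_k: int | None = None,
) -> ClusterAssignment:
    """Cluster over a range of k (default 1-5) and pick one assignment.

    The chosen k is the largest whose relative inertia improvement over
    k-1 reaches ``elbow_threshold`` (k = 1 when none does); ``force_k``
    overrides the rule.  All per-k assignments are attached as ``per_k``.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k range")
    per_k = {
        k: cluster_individuals(g, k, restarts, seed + k) for k in ks
    }
    if force_k is not None:
        if force_k not in per_k:
            per_k[force_k] = cluster_individuals(g, force_k, restarts, seed + force_k)
        chosen = per_k[force_k]
    else:
        chosen_k = ks[0]
        for prev, k in zip(ks[:-1], ks[1:]):
            i0, i1 = per_k[prev].inertia, per_k[k].inertia
            if i0 > 0 and (i0 - i1) / i0 >= elbow_threshold:
                chosen_k = k
        chosen = per_k[chosen_k]
    chosen.per_k = per_k
    return chosen


def _block_pairs(a_members, b_members=None):
    if b_members is None:
        return list(combinations(a_members, 2))
    return [(i, j) for i in a_members for j in b_members]


def stratified_kinship(
    g: GenotypeMatrix,
    assignment: ClusterAssignment,
    training_pairs: list[LabeledPair],
    *,
    restarts: int = 5,
    tol: float = 1e-6,
    maxiter: int = 400,
    epsilon: float = 1e-16,
):
    """Within- and between-cluster kinship with separately fitted models.

    For each cluster a model is fitted on the training pairs internal to
    it; for each cluster pair, on the training pairs spanning the two
    clusters (the individuals of both clusters pooled).  Every block
    needs at least one unrelated training pair or a fatal error names it.

    Returns (table, models): the merged estimate table carries a
    ``block`` column ("c<i>" within, "c<i>|c<j>" between) and covers
    every pair of individuals exactly once.
    """
    lab = assignment.labels
    for lp in training_pairs:
        g.index_of(lp.pair[0])
        g.index_of(lp.pair[1])
        if lp.pair[0] not in lab or lp.pair[1] not in lab:
            raise ValueError(f"training pair {lp.pair} not in cluster assignment")

    clusters = sorted(set(lab.values()))
    models = {}
    tables = []

    def fit_block(name, members_a, members_b, pair_filter):
        train = [lp for lp in training_pairs if pair_filter(lp)]
        if not any(lp.relationship == "UN" for lp in train):
            raise ValueError(
                f"block {name}: no unrelated training pairs; supply UN pairs "
                "for this cluster block"
            )
        fr = fit_p(g, train, restarts, tol=tol, maxiter=maxiter, epsilon=epsilon)
        models[name] = fr
        pairs = _block_pairs(members_a, members_b)
        if not pairs:
            return
        tab = kinship_matrix(g, fr.model, pairs)
        tab["block"] = name
        tables.append(tab)

    for c in clusters:
        members = assignment.members(c)
        if len(members) < 2:
            logger.info("cluster %d has a single member; no within pairs", c)
            continue
        fit_block(
            f"c{c}", members, None,
            lambda lp, c=c: lab[lp.pair[0]] == c and lab[lp.pair[1]] == c,
        )
    for a, b in combinations(clusters, 2):
        fit_block(
            f"c{a}|c{b}", assignment.members(a), assignment.members(b),
            lambda lp, a=a, b=b: {lab[lp.pair[0]], lab[lp.pair[1]]} == {a, b},
        )
    table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(
        columns=["id1", "id2", "n_sites", "distance", "phi_hat", "block"]
    )
    return table, models


def write_assignment(assignment: ClusterAssignment, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tcluster\n")
        for s, c in assignment.labels.items():
            fh.write(f"{s}\t{c}\n")
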