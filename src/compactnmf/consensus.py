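"""Consensus clustering over multiple seeded NMF restarts.

Single NMF runs suffer from the permutation problem: restarts reach equally
good factorizations whose components are shuffled.  Co-clustering counts are
permutation-free, so T restarts are aggregated into a sample x sample
consensus matrix C (fraction of runs in which two samples share the argmax
component), which is then cut by hierarchical clustering on 1 - C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .nmf import Factorization, factorize


@dataclass
class Clustering:
    """Per-sample labels in 1..k; ids assigned by decreasing cluster size."""

    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size and (self.labels.min() < 1 or self.labels.max() > self.k):
            raise ValueError("labels must lie in 1..k")

    def sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))


@dataclass
class ConsensusMatrix:
    """Symmetric co-clustering frequency matrix with unit diagonal."""

    values: np.ndarray
    runs: int
    rank: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def dissimilarity(self) -> np.ndarray:
        return 1.0 - self.values


def assign_clusters(W: np.ndarray) -> Clustering:
    """Assign each sample to its largest-weight component (ties: lowest index)."""
    W = np.asarray(W)
    if np.any(W.max(axis=1) == 0):
        raise ValueError("all-zero row in W: sample carries no cluster weight")
    return Clustering(labels=W.argmax(axis=1) + 1, k=W.shape[1])


def consensus_matrix(labelings: list[Clustering], rank: int | None = None) -> ConsensusMatrix:
    """C_ij = fraction of runs in which samples i and j share a label."""
    if not labelings:
        raise ValueError("need at least one labeling")
    n = len(labelings[0].labels)
    counts = np.zeros((n, n))
    for cl in labelings:
        lab = cl.labels
        if len(lab) != n:
            raise ValueError("labelings cover different sample sets")
        counts += lab[:, None] == lab[None, :]
    C = counts / len(labelings)
    return ConsensusMatrix(values=C, runs=len(labelings), rank=rank or labelings[0].k)


def _relabel_by_size(raw: np.ndarray, k: int) -> np.ndarray:
    """Renumber cluster ids 1..k by decreasing size (ties: first occurrence)."""
    ids, counts = np.unique(raw, return_counts=True)
    first = np.array([np.flatnonzero(raw == i)[0] for i in ids])
    order = sorted(range(len(ids)), key=lambda t: (-counts[t], first[t]))
    mapping = {ids[t]: new + 1 for new, t in enumerate(order)}
    return np.array([mapping[x] for x in raw])


def cut_clusters(C: ConsensusMatrix, k: int, method: str = "average") -> Clustering:
    """Agglomerative cut of the consensus tree into k groups."""
    n = C.n_samples
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    if n == 1 or k == n:
        return Clustering(labels=np.arange(1, n + 1) if k == n else np.ones(n, int), k=k)
    D = np.clip(C.dissimilarity(), 0.0, None)
    Z = linkage(squareform(D, checks=False), method=method)
    raw = fcluster(Z, k, criterion="maxclust")
    return Clustering(labels=_relabel_by_size(raw, k), k=k)


def stability_curve(
    labelings: list[Clustering],
    grid: list[int],
    reference: str = "all",
) -> list[tuple[int, float]]:
    """RMS off-diagonal change of the consensus matrix as runs accumulate.

    ``reference='all'`` compares the first-T consensus against the all-runs
    matrix; ``reference='consecutive'`` compares consecutive grid points.
    Small values mean additional restarts no longer move the matrix.
    """
    total = len(labelings)
    if any(t > total or t < 1 for t in grid):
        raise ValueError("grid values must lie in [1, total runs]")
    mats = {t: consensus_matrix(labelings[:t]).values for t in sorted(set(grid) | {total})}
    n = mats[total].shape[0]
    off = ~np.eye(n, dtype=bool)

    def rms(a: np.ndarray, b: np.ndarray) -> float:
        return float(np.sqrt(np.mean((a[off] - b[off]) ** 2))) if n > 1 else 0.0

    out = []
    prev_t = None
    for t in grid:
        if reference == "all":
            out.append((t, rms(mats[t], mats[total])))
        elif reference == "consecutive":
            out.append((t, 0.0 if prev_t is None else rms(mats[t], mats[prev_t])))
            prev_t = t
        else:
            raise ValueError(f"unknown reference {reference!r}")
    return out


def run_consensus(
    Vc,
    k: int,
    T: int,
    base_seed: int,
    max_iter: int = 2000,
    tol: float = 1e-6,
    linkage_method: str = "average",
) -> tuple[ConsensusMatrix, Clustering, list[dict]]:
    """T seeded restarts (seeds base_seed..base_seed+T-1) -> consensus -> cut.

    Returns the consensus matrix, the final k-group clustering and a per-run
    log of seed, iterations and achieved divergence.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    values = getattr(Vc, "values", Vc)
    labelings: list[Clustering] = []
    log: list[dict] = []
    for t in range(T):
        seed = base_seed + t
        f: Factorization = factorize(values, k, seed=seed, max_iter=max_iter, tol=tol)
        labelings.append(assign_clusters(f.W))
        log.append({"seed": seed, "iterations": f.iterations, "divergence": f.divergence})
    C = consensus_matrix(labelings, rank=k)
    return C, cut_clusters(C, k, method=linkage_method), log
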