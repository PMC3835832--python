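"""Rank-selection measures and cluster/label association testing.

The number of factorization components k (the candidate number of patient
subgroups) is chosen by weighing several unsupervised measures computed from
the consensus matrix: the intra-cluster similarity family S(k) (mean, median
or max over clusters of the average pairwise co-clustering frequency inside
each cluster), the cophenetic correlation of the consensus dendrogram, and
the mean silhouette on the consensus dissimilarity.  Association of the
final clusters with external categorical labels (e.g. molecular subtype) is
tested with an exact conditional r x c Fisher test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .consensus import Clustering, ConsensusMatrix, cut_clusters, run_consensus

_AGGREGATORS = {"mean": np.mean, "median": np.median, "max": np.max}


@dataclass
class QualityReport:
    """Per-rank table of rank-selection measures plus the chosen clusterings."""

    table: pd.DataFrame
    clusterings: dict[int, Clustering]
    consensus: dict[int, ConsensusMatrix]
    recommended_rank: int
    per_cluster_similarity: dict[int, dict[int, float]] = field(default_factory=dict)


def intra_cluster_similarity(
    C: ConsensusMatrix,
    clustering: Clustering,
    aggregator: str = "mean",
    include_singletons: bool = True,
) -> tuple[float, dict[int, float]]:
    """Aggregate of per-cluster mean pairwise consensus.

    Per cluster with >= 2 members: the mean of C_ij over unordered within-
    cluster pairs.  Singletons score 1 by convention (a sample always
    co-clusters with itself); they can inflate the max aggregator, so
    ``include_singletons=False`` drops them from the aggregation.
    """
    if aggregator not in _AGGREGATORS:
        raise ValueError(f"unknown aggregator {aggregator!r}")
    labels = clustering.labels
    if len(labels) != C.n_samples:
        raise ValueError("clustering does not match consensus matrix samples")
    per_cluster: dict[int, float] = {}
    for c in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == c)
        if len(idx) == 1:
            per_cluster[c] = 1.0
        else:
            sub = C.values[np.ix_(idx, idx)]
            iu = np.triu_indices(len(idx), k=1)
            per_cluster[c] = float(np.mean(sub[iu]))
    vals = [
        v for c, v in per_cluster.items()
        if include_singletons or np.count_nonzero(labels == c) > 1
    ]
    if not vals:
        raise ValueError("no clusters left to aggregate")
    return float(_AGGREGATORS[aggregator](vals)), per_cluster


def cophenetic_coefficient(C: ConsensusMatrix, method: str = "average") -> float:
    """Correlation between consensus dissimilarities and dendrogram distances."""
    if C.n_samples < 3:
        raise ValueError("need at least 3 samples")
    d = squareform(np.clip(C.dissimilarity(), 0.0, None), checks=False)
    if np.ptp(d) == 0:
        raise ValueError("constant dissimilarities: cophenetic correlation undefined")
    Z = linkage(d, method=method)
    coeff, coph_d = cophenet(Z, d)
    if np.ptp(coph_d) == 0:
        raise ValueError("constant cophenetic distances: correlation undefined")
    return float(coeff)


def silhouette_mean(C: ConsensusMatrix, clustering: Clustering) -> float:
    """Mean silhouette on the consensus dissimilarity (singletons score 0)."""
    labels = clustering.labels
    k = len(set(labels.tolist()))
    if k < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    if k == C.n_samples:  # all singletons: every sample scores 0
        return 0.0
    D = np.clip(C.dissimilarity(), 0.0, None)
    np.fill_diagonal(D, 0.0)
    return float(silhouette_score(D, labels, metric="precomputed"))


def rank_report(
    Vc,
    ranks: list[int],
    T: int,
    base_seed: int,
    max_iter: int = 2000,
    tol: float = 1e-6,
    linkage_method: str = "average",
) -> QualityReport:
    """Run consensus at each rank and tabulate all rank-selection measures.

    The recommended rank is the argmax of the mean intra-cluster similarity
    S_mean (ties to the smaller rank) — a reporting default; the full table
    is meant for human adjudication across measures.
    """
    if not ranks:
        raise ValueError("ranks must be nonempty")
    rows = []
    clusterings: dict[int, Clustering] = {}
    consensus: dict[int, ConsensusMatrix] = {}
    per_cluster_all: dict[int, dict[int, float]] = {}
    for k in ranks:
        C, cl, _ = run_consensus(
            Vc, k, T, base_seed, max_iter=max_iter, tol=tol, linkage_method=linkage_method
        )
        s_mean, per_cluster = intra_cluster_similarity(C, cl, "mean")
        s_median, _ = intra_cluster_similarity(C, cl, "median")
        s_max, _ = intra_cluster_similarity(C, cl, "max")
        try:
            coph = cophenetic_coefficient(C, method=linkage_method)
        except ValueError:
            coph = float("nan")
        sil = silhouette_mean(C, cl) if k >= 2 else float("nan")
        sizes = cl.sizes()
        rows.append(
            {
                "rank": k,
                "S_mean": s_mean,
                "S_median": s_median,
                "S_max": s_max,
                "cophenetic": coph,
                "silhouette": sil,
                "cluster_sizes": ",".join(str(sizes[c]) for c in sorted(sizes)),
            }
        )
        clusterings[k] = cl
        consensus[k] = C
        per_cluster_all[k] = per_cluster
    table = pd.DataFrame(rows)
    s_vals = table["S_mean"].to_numpy()
    recommended = int(table.loc[s_vals == s_vals.max(), "rank"].min())
    return QualityReport(
        table=table,
        clusterings=clusterings,
        consensus=consensus,
        recommended_rank=recommended,
        per_cluster_similarity=per_cluster_all,
    )


# ---------------------------------------------------------------------------
# exact conditional test for r x c contingency tables


def _log_table_prob(table: np.ndarray, log_fact: np.ndarray, const: float) -> float:
    return const - log_fact[table].sum()


def fisher_exact(table, max_tables: int = 5_000_000) -> float:
    """Two-sided exact conditional p-value for an r x c contingency table.

    All tables with the observed margins are enumerated; the p-value sums the
    multivariate hypergeometric probabilities of tables no more probable than
    the observed one (probability-ordering convention).  ``max_tables`` caps
    the enumeration; larger problems raise, advising a Monte-Carlo approach.
    """
    raw = np.asarray(table, dtype=float)
    if raw.ndim != 2 or raw.shape[0] < 2 or raw.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if np.any(raw < 0) or np.any(raw != np.round(raw)):
        raise ValueError("table entries must be non-negative integers")
    obs = raw.astype(int)
    N = int(obs.sum())
    if N == 0:
        raise ValueError("table total must be positive")
    row_sums = obs.sum(axis=1)
    col_sums = obs.sum(axis=0)

    # crude upper bound on the number of candidate tables
    bound = 1.0
    for r in row_sums[:-1]:
        for c in col_sums[:-1]:
            bound *= min(r, c) + 1
            if bound > max_tables:
                raise ValueError(
                    "contingency table too large for exact enumeration; "
                    "use a Monte-Carlo approximation instead"
                )

    log_fact = np.append(0.0, np.cumsum(np.log(np.arange(1, N + 1))))
    const = log_fact[row_sums].sum() + log_fact[col_sums].sum() - log_fact[N]
    obs_logp = _log_table_prob(obs, log_fact, const)
    cutoff = obs_logp + 1e-7  # tolerate ties up to rounding

    r, c = obs.shape
    total_p = 0.0
    work = np.zeros((r, c), dtype=int)

    def fill_row(i: int, j: int, row_left: int, col_left: np.ndarray) -> None:
        nonlocal total_p
        if i == r - 1:
            work[i] = col_left
            if _log_table_prob(work, log_fact, const) <= cutoff:
                total_p += math.exp(_log_table_prob(work, log_fact, const))
            return
        if j == c - 1:
            if row_left > col_left[j]:
                return
            work[i, j] = row_left
            col_left[j] -= row_left
            fill_row(i + 1, 0, int(row_sums[i + 1]), col_left)
            col_left[j] += row_left
            return
        hi = min(row_left, int(col_left[j]))
        for v in range(hi + 1):
            work[i, j] = v
            col_left[j] -= v
            fill_row(i, j + 1, row_left - v, col_left)
            col_left[j] += v

    fill_row(0, 0, int(row_sums[0]), col_sums.copy())
    return min(total_p, 1.0)
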