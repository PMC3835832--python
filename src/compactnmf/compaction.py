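"""Column compaction by Hamming distance under a genomic-locality window.

High-resolution CN matrices carry heavy column redundancy: neighbouring
probes inside one aberrant segment produce (near-)identical columns.  A
greedy single pass per (channel, chromosome) block groups columns whose
Hamming distance to the bin's seed column is at most ``delta`` and whose
probe ordinal lies within ``window`` of the seed's, then sums each bin into
one compacted column.  ``delta=0`` with an unbounded window is lossless:
factorizing the compacted matrix solves exactly the original NMF problem.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encoding import FeatureMatrix


@dataclass
class BinPartition:
    """Ordered partition of feature indices into bins.

    ``bins[b]`` lists the feature (column) indices of bin ``b`` in genomic
    order; ``representative[b]`` is the seed column the greedy pass opened
    the bin with (always ``bins[b][0]``).
    """

    bins: list[list[int]]
    representative: list[int]
    delta: int
    window: int | None

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def n_features(self) -> int:
        return sum(len(b) for b in self.bins)

    def sizes(self) -> np.ndarray:
        return np.array([len(b) for b in self.bins])

    def validate_against(self, n_features: int) -> None:
        seen = sorted(j for b in self.bins for j in b)
        if seen != list(range(n_features)):
            raise ValueError("bins do not partition the feature indices")


@dataclass
class CompactMatrix:
    """Bin-summed matrix: column b is the elementwise sum of bin b's columns."""

    values: np.ndarray
    partition: BinPartition

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


def hamming_distance(col_a: np.ndarray, col_b: np.ndarray) -> int:
    """Number of row positions where the two columns differ exactly (0.5 != 0 != 1)."""
    a = np.asarray(col_a)
    b = np.asarray(col_b)
    if a.shape != b.shape:
        raise ValueError(f"column length mismatch: {a.shape} vs {b.shape}")
    return int(np.count_nonzero(a != b))


def default_delta(m: int) -> int:
    """Hamming threshold for the 1%-of-a-column rule: ceil(0.01 * m)."""
    if m < 1:
        raise ValueError("sample count must be >= 1")
    return math.ceil(0.01 * m)


def build_partition(F: FeatureMatrix, delta: int, window: int | None = 500) -> BinPartition:
    """Greedy left-to-right binning per (channel, chromosome) block.

    Within each block, in genomic order, the first unassigned column seeds a
    bin; every later unassigned column of the block joins it if its probe
    ordinal is within ``window`` of the seed's and its Hamming distance to
    the seed column is at most ``delta``.  Columns are never compared across
    channels or chromosomes.  ``window=None`` disables the locality limit.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if window is not None and window < 0:
        raise ValueError("window must be >= 0")
    meta = F.feature_meta
    values = F.values
    bins: list[list[int]] = []
    reps: list[int] = []
    for _, block in meta.groupby(["channel", "chrom"], sort=False):
        cols = block.index.to_numpy()  # genomic order within block
        ordinals = block["probe_index"].to_numpy()
        unassigned = np.ones(len(cols), dtype=bool)
        for s in range(len(cols)):
            if not unassigned[s]:
                continue
            unassigned[s] = False
            members = [int(cols[s])]
            cand = np.flatnonzero(unassigned)
            cand = cand[cand > s]
            if window is not None:
                cand = cand[np.abs(ordinals[cand] - ordinals[s]) <= window]
            if len(cand):
                seed_col = values[:, cols[s]][:, None]
                dists = np.count_nonzero(values[:, cols[cand]] != seed_col, axis=0)
                joins = cand[dists <= delta]
                members.extend(int(cols[j]) for j in joins)
                unassigned[joins] = False
            bins.append(members)
            reps.append(members[0])
    return BinPartition(bins=bins, representative=reps, delta=delta, window=window)


def compact(F: FeatureMatrix, P: BinPartition) -> CompactMatrix:
    """Sum each bin's columns into one compacted column."""
    P.validate_against(F.n_features)
    values = np.empty((F.n_samples, P.n_bins))
    for b, members in enumerate(P.bins):
        values[:, b] = F.values[:, members].sum(axis=1)
    return CompactMatrix(values=values, partition=P)


def reduce_standard(F: FeatureMatrix, P: BinPartition) -> FeatureMatrix:
    """Keep only each bin's representative column (the discarding baseline)."""
    P.validate_against(F.n_features)
    keep = list(P.representative)
    return FeatureMatrix(
        values=F.values[:, keep],
        feature_meta=F.feature_meta.iloc[keep].reset_index(drop=True),
        samples=list(F.samples),
    )


def compaction_summary(F: FeatureMatrix, deltas: list[int], window: int | None = 500) -> pd.DataFrame:
    """Column count remaining at each Hamming threshold (delta -> n_bins)."""
    rows = [
        {"delta": d, "n_columns": build_partition(F, d, window).n_bins}
        for d in deltas
    ]
    return pd.DataFrame(rows)


def write_partition(P: BinPartition, path) -> None:
    rows = [
        {"bin": b, "seed": P.representative[b], "members": ",".join(map(str, members))}
        for b, members in enumerate(P.bins)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_partition(path, delta: int | None = None, window: int | None = None) -> BinPartition:
    table = pd.read_csv(path, sep="\t", dtype={"members": str})
    bins = [[int(x) for x in m.split(",")] for m in table["members"]]
    return BinPartition(
        bins=bins, representative=[int(s) for s in table["seed"]],
        delta=-1 if delta is None else delta, window=window,
    )
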