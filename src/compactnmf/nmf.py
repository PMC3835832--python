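"""KL-divergence NMF by multiplicative updates, with compact-factor expansion.

The objective is the generalized Kullback-Leibler (Poisson) divergence

    D(V || WH) = sum_ij  V_ij log(V_ij / (WH)_ij) - V_ij + (WH)_ij

minimized over non-negative W (samples x rank) and H (rank x columns) by the
classic multiplicative updates, which never increase D.  When NMF is run on
a bin-summed compact matrix, ``expand_H`` maps the compact H back to the
original columns (each bin column divided by its size), so the divergence to
the *full* matrix can be evaluated and compared across compaction levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compaction import BinPartition

EPS = 1e-12


@dataclass
class Factorization:
    W: np.ndarray
    H: np.ndarray
    rank: int
    seed: int | None
    iterations: int
    divergence: float


def kl_divergence(V: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Generalized KL divergence D(V || WH); +inf if V>0 where (WH)=0."""
    V = np.asarray(V, dtype=float)
    WH = np.asarray(W, dtype=float) @ np.asarray(H, dtype=float)
    if np.any((WH == 0) & (V > 0)):
        return float("inf")
    WH = np.maximum(WH, EPS)
    pos = V > 0
    div = np.sum(V[pos] * np.log(V[pos] / WH[pos])) - V.sum() + WH.sum()
    return float(div)


def update_step(V: np.ndarray, W: np.ndarray, H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One multiplicative update: H first with current W, then W with the new H."""
    V = np.asarray(V, dtype=float)
    WH = np.maximum(W @ H, EPS)
    H = H * (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], EPS)
    H = np.maximum(H, EPS)
    WH = np.maximum(W @ H, EPS)
    W = W * ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], EPS)
    W = np.maximum(W, EPS)
    return W, H


def factorize(
    V: np.ndarray,
    k: int,
    seed: int,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> Factorization:
    """Seeded multiplicative-update NMF run.

    W and H start uniform at random in (0, 1]; updates stop when the relative
    divergence improvement drops below ``tol`` or after ``max_iter`` steps.
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("input matrix must be finite")
    if np.any(V < 0):
        raise ValueError("input matrix must be non-negative")
    m, n = V.shape
    if k < 1 or k > min(m, n):
        raise ValueError(f"rank {k} outside [1, {min(m, n)}]")
    rng = np.random.default_rng(seed)
    # uniform over (0, 1]
    W = 1.0 - rng.random((m, k))
    H = 1.0 - rng.random((k, n))
    prev = kl_divergence(V, W, H)
    iterations = 0
    for iterations in range(1, max_iter + 1):
        W, H = update_step(V, W, H)
        div = kl_divergence(V, W, H)
        if prev > 0 and (prev - div) / max(prev, EPS) < tol:
            prev = div
            break
        prev = div
    return Factorization(W=W, H=H, rank=k, seed=seed, iterations=iterations, divergence=prev)


def expand_H(Hc: np.ndarray, P: BinPartition) -> np.ndarray:
    """Map a compact H (rank x bins) back to original columns.

    Original column j gets its bin's H column divided by the bin size; for
    lossless bins (identical columns) this reproduces the full-matrix
    divergence of the compact solution exactly.
    """
    Hc = np.asarray(Hc, dtype=float)
    if Hc.shape[1] != P.n_bins:
        raise ValueError(f"H has {Hc.shape[1]} columns but partition has {P.n_bins} bins")
    H = np.empty((Hc.shape[0], P.n_features))
    for b, members in enumerate(P.bins):
        H[:, members] = (Hc[:, b] / len(members))[:, None]
    return H


def replicate_H(Hc: np.ndarray, P: BinPartition) -> np.ndarray:
    """Copy each bin representative's H column to every member, undivided.

    This is how a discarding baseline models the columns it never saw: each
    original column is assumed identical to its bin's kept representative.
    """
    Hc = np.asarray(Hc, dtype=float)
    if Hc.shape[1] != P.n_bins:
        raise ValueError(f"H has {Hc.shape[1]} columns but partition has {P.n_bins} bins")
    H = np.empty((Hc.shape[0], P.n_features))
    for b, members in enumerate(P.bins):
        H[:, members] = Hc[:, b][:, None]
    return H


def full_divergence(
    V_full, W: np.ndarray, Hc: np.ndarray, P: BinPartition, mode: str = "compact"
) -> float:
    """Divergence of a compacted/reduced factorization to the whole matrix."""
    values = getattr(V_full, "values", V_full)
    if mode == "compact":
        return kl_divergence(values, W, expand_H(Hc, P))
    if mode == "standard":
        return kl_divergence(values, W, replicate_H(Hc, P))
    raise ValueError(f"unknown mode {mode!r}")


def divergence_ratio(
    V_full,
    P: BinPartition,
    k: int,
    seeds: list[int],
    mode: str,
    reference_partition: BinPartition | None = None,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> float:
    """Mean full-matrix divergence of ``mode`` runs over the Full-NMF mean.

    The reference is NMF on the lossless (delta=0) compaction of the same
    matrix, run with the same seeds; ``reference_partition`` must be that
    delta=0 partition (built by the caller, typically once per matrix).
    """
    from .compaction import build_partition, compact, reduce_standard
    from .encoding import FeatureMatrix

    if mode not in ("compact", "standard"):
        raise ValueError(f"unknown mode {mode!r}")
    if not isinstance(V_full, FeatureMatrix):
        raise TypeError("V_full must be a FeatureMatrix")
    if reference_partition is None:
        reference_partition = build_partition(V_full, delta=0, window=None)

    if mode == "compact":
        Vc = compact(V_full, P).values
    else:
        Vc = reduce_standard(V_full, P).values
    Vref = compact(V_full, reference_partition).values

    target = []
    reference = []
    for seed in seeds:
        f = factorize(Vc, k, seed=seed, max_iter=max_iter, tol=tol)
        target.append(full_divergence(V_full, f.W, f.H, P, mode=mode))
        r = factorize(Vref, k, seed=seed, max_iter=max_iter, tol=tol)
        reference.append(full_divergence(V_full, r.W, r.H, reference_partition, mode="compact"))
    ref_mean = float(np.mean(reference))
    if ref_mean == 0:
        raise ValueError("reference (Full-NMF) divergence is zero")
    return float(np.mean(target)) / ref_mean
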