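"""Encoding of discrete copy-number / LOH calls into non-negative feature matrices.

Copy-number (CN) calls are integers (0 = homozygous deletion, 1 = heterozygous
loss, 2 = normal, 3-4 = gain, >4 = amplification) or discrete states
(``loss`` / ``normal`` / ``gain``).  Because the Poisson-likelihood NMF
objective is asymmetric, gains and losses are separated into two non-negative
channels per probe: aberration severity goes up in its own channel and normal
is 0 in both.  Copy-neutral LOH (normal CN but loss of heterozygosity) is a
milder loss-like lesion and is encoded 0.5 in the loss channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STATES = ("loss", "normal", "gain")

#: severity encoding per channel for integer copy numbers (ordinal scheme)
_GAIN_ORDINAL = {3: 1.0, 4: 1.0}  # CN>4 handled separately -> 2
_LOSS_ORDINAL = {1: 1.0, 0: 2.0}


@dataclass
class CNProfileSet:
    """Discrete copy-number calls for a cohort.

    Parameters
    ----------
    samples
        Sample identifiers, one per matrix row.
    probes
        DataFrame with columns ``probe``, ``chrom``, ``position`` sorted by
        (chrom, position); one row per probe, in the column order of ``calls``.
    calls
        sample x probe array of integer copy numbers, or of objects in
        ``{"loss", "normal", "gain"}``.
    loh
        Optional sample x probe boolean array flagging copy-neutral LOH.
    """

    samples: list[str]
    probes: pd.DataFrame
    calls: np.ndarray
    loh: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls)
        if self.calls.shape != (len(self.samples), len(self.probes)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.probes)} probes"
            )
        for col in ("probe", "chrom", "position"):
            if col not in self.probes.columns:
                raise ValueError(f"probe annotation lacks column {col!r}")
        for chrom, grp in self.probes.groupby("chrom", sort=False):
            pos = grp["position"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"probe positions not strictly increasing on {chrom}")
        if self.is_integer:
            if np.any(self.calls < 0):
                raise ValueError("negative copy numbers are not allowed")
        else:
            bad = set(np.unique(self.calls)) - set(STATES)
            if bad:
                raise ValueError(f"unknown discrete states: {sorted(bad)}")
        if self.loh is not None:
            self.loh = np.asarray(self.loh, dtype=bool)
            if self.loh.shape != self.calls.shape:
                raise ValueError("loh flags must match calls shape")

    @property
    def is_integer(self) -> bool:
        return np.issubdtype(self.calls.dtype, np.number)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_probes(self) -> int:
        return len(self.probes)


@dataclass
class FeatureMatrix:
    """Non-negative sample x feature matrix consumed by the factorization.

    Exactly two features (columns) per probe: all loss-channel columns first
    in genomic order, then all gain-channel columns.  The layout is recorded
    per column in ``feature_meta`` (columns ``probe``, ``chrom``, ``position``,
    ``probe_index``, ``channel``) so downstream code never relies on it.
    """

    values: np.ndarray
    feature_meta: pd.DataFrame
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("feature matrix must be non-negative")
        if self.values.shape[1] != len(self.feature_meta):
            raise ValueError("feature_meta rows must match value columns")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def expand_segments(segments: pd.DataFrame, probe_annotation: pd.DataFrame) -> CNProfileSet:
    """Expand segment-level calls (sample, chrom, start, end, state) to probes.

    Coordinates are 1-based inclusive.  Probes not covered by any segment are
    ``normal``.  Overlapping segments for one sample on one chromosome are an
    error.  Samples appear in the output in order of first appearance.
    """
    if len(probe_annotation) == 0:
        raise ValueError("probe annotation is empty")
    required = {"sample", "chrom", "start", "end", "state"}
    missing = required - set(segments.columns)
    if missing:
        raise ValueError(f"segment table lacks columns {sorted(missing)}")
    bad_states = set(segments["state"]) - set(STATES)
    if bad_states:
        raise ValueError(f"unknown segment states: {sorted(bad_states)}")

    probes = probe_annotation.sort_values(["chrom", "position"], kind="stable").reset_index(drop=True)
    samples = list(dict.fromkeys(segments["sample"]))
    calls = np.full((len(samples), len(probes)), "normal", dtype=object)
    sample_idx = {s: i for i, s in enumerate(samples)}

    for (sample, chrom), grp in segments.groupby(["sample", "chrom"], sort=False):
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if np.any(starts[1:] <= ends[:-1]):
            raise ValueError(f"overlapping segments for sample {sample!r} on {chrom}")
        on_chrom = probes["chrom"] == chrom
        pos = probes.loc[on_chrom, "position"].to_numpy()
        cols = np.flatnonzero(on_chrom.to_numpy())
        for start, end, state in zip(starts, ends, grp["state"]):
            inside = (pos >= start) & (pos <= end)
            calls[sample_idx[sample], cols[inside]] = state
    return CNProfileSet(samples=samples, probes=probes, calls=calls)


def encode(profiles: CNProfileSet, scheme: str = "ordinal") -> FeatureMatrix:
    """Encode CN calls into the two-channel feature matrix.

    ``ordinal`` (integer CN required): gain channel 1 for CN in {3,4}, 2 for
    CN>4; loss channel 1 for CN=1, 2 for CN=0, and 0.5 for copy-neutral LOH
    (loh flag with CN=2).  ``binary``: 1 for the presence of the aberration in
    the matching channel, from either integer CN (gain iff CN>=3, loss iff
    CN<=1) or discrete states; LOH flags are ignored with a warning.
    """
    if scheme not in ("ordinal", "binary"):
        raise ValueError(f"unknown encoding scheme {scheme!r}")
    calls = profiles.calls
    if scheme == "ordinal":
        if not profiles.is_integer:
            raise ValueError("ordinal scheme requires integer copy numbers")
        cn = calls.astype(int)
        gain = np.where(cn > 4, 2.0, np.where(cn >= 3, 1.0, 0.0))
        loss = np.where(cn == 0, 2.0, np.where(cn == 1, 1.0, 0.0))
        if profiles.loh is not None:
            loss = np.where(profiles.loh & (cn == 2), 0.5, loss)
    else:
        if profiles.loh is not None:
            warnings.warn("binary scheme ignores copy-neutral LOH flags", stacklevel=2)
        if profiles.is_integer:
            cn = calls.astype(int)
            gain = (cn >= 3).astype(float)
            loss = (cn <= 1).astype(float)
        else:
            gain = (calls == "gain").astype(float)
            loss = (calls == "loss").astype(float)

    meta_one = profiles.probes[["probe", "chrom", "position"]].copy()
    meta_one["probe_index"] = np.arange(len(meta_one))
    loss_meta = meta_one.copy()
    loss_meta["channel"] = "loss"
    gain_meta = meta_one.copy()
    gain_meta["channel"] = "gain"
    meta = pd.concat([loss_meta, gain_meta], ignore_index=True)
    values = np.hstack([loss, gain])
    return FeatureMatrix(values=values, feature_meta=meta, samples=list(profiles.samples))


# ---------------------------------------------------------------------------
# tab-delimited I/O


def read_probe_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"probe": str, "chrom": str})
    return ann[["probe", "chrom", "position"]]


def read_probe_matrix(path, annotation_path) -> CNProfileSet:
    """Read a probe-call matrix (first column sample id, header of probe ids)."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    probes = read_probe_annotation(annotation_path)
    probes = probes.sort_values(["chrom", "position"], kind="stable").reset_index(drop=True)
    missing = set(probes["probe"]) - set(table.columns)
    if missing:
        raise ValueError(f"{len(missing)} annotated probes missing from matrix")
    table = table[probes["probe"].tolist()]
    if table.isna().any().any():
        raise ValueError("missing calls in probe matrix; complete profiles required")
    calls = table.to_numpy()
    if calls.dtype == object:
        calls = calls.astype(str).astype(object)
    return CNProfileSet(samples=[str(s) for s in table.index], probes=probes, calls=calls)


def read_segments(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str, "state": str})


def write_probe_matrix(profiles: CNProfileSet, matrix_path, annotation_path) -> None:
    pd.DataFrame(
        profiles.calls, index=pd.Index(profiles.samples, name="sample"),
        columns=profiles.probes["probe"],
    ).to_csv(matrix_path, sep="\t")
    profiles.probes[["probe", "chrom", "position"]].to_csv(annotation_path, sep="\t", index=False)
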