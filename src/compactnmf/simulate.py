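"""Synthetic probe-level copy-number cohorts with planted subgroups.

Each subgroup is defined by contiguous aberration blocks (a chromosome
region gained or lost, carried by each member independently with a given
penetrance).  Whole blocks toggling together produce the runs of identical
or near-identical columns that compaction exploits, mimicking real
segmented CN profiles where neighbouring probes inside one lesion share a
state.  Background noise flips single probes to a mild aberration with no
spatial correlation, so all spatial signal comes from the planted blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .encoding import CNProfileSet

# integer CN used per (channel, severity)
_SEVERITY_CN = {("gain", 1): 3, ("gain", 2): 5, ("loss", 1): 1, ("loss", 2): 0}


@dataclass
class AberrationBlock:
    """A contiguous planted lesion: probes [start, end) on one chromosome."""

    chrom: str
    start: int  # probe ordinal within chromosome, inclusive
    end: int  # exclusive
    channel: str  # "gain" or "loss"
    penetrance: float = 1.0
    severity: int = 1


@dataclass
class SyntheticSpec:
    """Geometry and signal of a planted-subgroup CN cohort.

    ``samples_per_group`` defines k; ``blocks_per_group[g]`` lists the
    lesions carried (each with its penetrance) by members of group g.
    ``background_rate`` is the per-probe probability of an independent
    severity-1 aberration in a random direction.
    """

    samples_per_group: list[int]
    probes_per_chrom: list[int]
    blocks_per_group: list[list[AberrationBlock]]
    background_rate: float = 0.0
    loh_blocks: list[list[AberrationBlock]] | None = None
    seed: int = 0

    def validate(self) -> None:
        errors = []
        if len(self.blocks_per_group) != len(self.samples_per_group):
            errors.append("blocks_per_group must have one entry per group")
        if any(n < 1 for n in self.samples_per_group):
            errors.append("each group needs at least one sample")
        if not 0 <= self.background_rate <= 1:
            errors.append("background_rate must lie in [0, 1]")
        chrom_sizes = {f"chr{i + 1}": n for i, n in enumerate(self.probes_per_chrom)}
        all_blocks = [b for grp in self.blocks_per_group for b in grp]
        if self.loh_blocks:
            all_blocks += [b for grp in self.loh_blocks for b in grp]
        for b in all_blocks:
            if b.chrom not in chrom_sizes:
                errors.append(f"block on unknown chromosome {b.chrom}")
            elif not 0 <= b.start < b.end <= chrom_sizes[b.chrom]:
                errors.append(f"block {b.chrom}:{b.start}-{b.end} outside chromosome bounds")
            if not 0 <= b.penetrance <= 1:
                errors.append(f"block {b.chrom}:{b.start}-{b.end} penetrance outside [0, 1]")
            if b.severity not in (1, 2):
                errors.append(f"block {b.chrom}:{b.start}-{b.end} severity must be 1 or 2")
            if b.channel not in ("gain", "loss"):
                errors.append(f"block {b.chrom}:{b.start}-{b.end} unknown channel {b.channel!r}")
        if errors:
            raise ValueError("invalid synthetic spec: " + "; ".join(errors))


@dataclass
class SyntheticDataset:
    profiles: CNProfileSet
    labels: np.ndarray  # true group per sample, 1..k
    spec: SyntheticSpec = field(repr=False)


def default_spec(seed: int = 0) -> SyntheticSpec:
    """Three-group design: 60 samples x 2,000 probes, penetrance 0.9, noise 0.02.

    A desk-scale rendition of a segmented SNP-array cohort: four chromosomes
    of 500 probes, each group marked by two 120-probe lesions.
    """
    blocks = [
        [
            AberrationBlock("chr1", 60, 180, "gain", 0.9),
            AberrationBlock("chr2", 300, 420, "loss", 0.9),
        ],
        [
            AberrationBlock("chr2", 40, 160, "gain", 0.9),
            AberrationBlock("chr3", 250, 370, "loss", 0.9),
        ],
        [
            AberrationBlock("chr3", 30, 150, "gain", 0.9),
            AberrationBlock("chr4", 200, 320, "loss", 0.9),
        ],
    ]
    return SyntheticSpec(
        samples_per_group=[25, 20, 15],
        probes_per_chrom=[500, 500, 500, 500],
        blocks_per_group=blocks,
        background_rate=0.02,
        seed=seed,
    )


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw a cohort: block lesions per sample at their penetrance, plus noise."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_samples = sum(spec.samples_per_group)
    probe_rows = []
    offsets = {}
    ordinal = 0
    for ci, n_probes in enumerate(spec.probes_per_chrom):
        chrom = f"chr{ci + 1}"
        offsets[chrom] = ordinal
        for p in range(n_probes):
            probe_rows.append((f"p{ordinal:05d}", chrom, (p + 1) * 1000))
            ordinal += 1
    probes = pd.DataFrame(probe_rows, columns=["probe", "chrom", "position"])
    n_probes_total = ordinal

    cn = np.full((n_samples, n_probes_total), 2, dtype=int)
    labels = np.empty(n_samples, dtype=int)
    row = 0
    for g, n_in_group in enumerate(spec.samples_per_group):
        for _ in range(n_in_group):
            labels[row] = g + 1
            for block in spec.blocks_per_group[g]:
                if rng.random() < block.penetrance:
                    cols = slice(
                        offsets[block.chrom] + block.start, offsets[block.chrom] + block.end
                    )
                    cn[row, cols] = _SEVERITY_CN[(block.channel, block.severity)]
            row += 1

    if spec.background_rate > 0:
        hits = rng.random(cn.shape) < spec.background_rate
        direction = rng.random(cn.shape) < 0.5  # True -> gain
        cn[hits & direction] = _SEVERITY_CN[("gain", 1)]
        cn[hits & ~direction] = _SEVERITY_CN[("loss", 1)]

    loh = None
    if spec.loh_blocks:
        loh = np.zeros(cn.shape, dtype=bool)
        row = 0
        for g, n_in_group in enumerate(spec.samples_per_group):
            for _ in range(n_in_group):
                for block in spec.loh_blocks[g]:
                    if rng.random() < block.penetrance:
                        cols = slice(
                            offsets[block.chrom] + block.start, offsets[block.chrom] + block.end
                        )
                        loh[row, cols] = True
                row += 1
        loh &= cn == 2  # copy-neutral only

    samples = [f"S{i:03d}" for i in range(n_samples)]
    profiles = CNProfileSet(samples=samples, probes=probes, calls=cn, loh=loh)
    return SyntheticDataset(profiles=profiles, labels=labels, spec=spec)


def adjusted_rand(labels_a, labels_b) -> float:
    """Chance-corrected pair-counting agreement between two labelings."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("labelings must cover the same samples")
    return float(adjusted_rand_score(a, b))


def pair_agreement_rand(labels_a, labels_b) -> float:
    """Brute-force adjusted Rand by explicit pair enumeration (test oracle)."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("labelings must cover the same samples")
    n = len(a)
    both = same_a = same_b = 0
    n_pairs = n * (n - 1) // 2
    for i, j in combinations(range(n), 2):
        sa = a[i] == a[j]
        sb = b[i] == b[j]
        same_a += sa
        same_b += sb
        both += sa and sb
    expected = same_a * same_b / n_pairs if n_pairs else 0.0
    max_index = (same_a + same_b) / 2
    if max_index == expected:
        return 1.0
    return (both - expected) / (max_index - expected)
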