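# compactnmf

Discovery of patient subgroups from DNA copy-number (CN) profiles by
non-negative matrix factorization (NMF) on *compacted* matrices, with
consensus clustering over multiple restarts and intra-cluster-similarity
rank selection.

High-resolution SNP/aCGH arrays yield hundreds of thousands of probe-level
CN calls per sample, far beyond what KL-divergence NMF can factorize
directly. Because segmented CN profiles are massively redundant —
neighbouring probes inside one lesion share a state — similar matrix
columns can be grouped into bins and **summed**, and NMF run on the small
bin-summed matrix while still (approximately) minimizing the divergence to
the *original* matrix. This is the package's core, in contrast to the usual
practice of simply discarding all but one column per group, which optimizes
the wrong objective and measurably degrades the fit.

## Model

Samples are rows of a non-negative matrix `V` (m × n). Two features per
probe separate gains from losses, because the Poisson-likelihood objective
is asymmetric: with integer CN calls, normal = 0, heterozygous loss / gain
= 1, homozygous deletion / amplification = 2 in the matching channel, and
copy-neutral LOH = 0.5 in the loss channel; binary cohorts use 0/1
presence calls. NMF seeks `W` (m × k) and `H` (k × n), all entries ≥ 0,
minimizing the generalized Kullback–Leibler divergence

    D(V ∥ WH) = Σ_ij [ V_ij log(V_ij / (WH)_ij) − V_ij + (WH)_ij ]

by the standard multiplicative updates, which never increase `D`.

**Compaction.** A partition `P` of the columns into bins — built by a
greedy pass that groups columns whose Hamming distance to the bin's seed is
≤ δ (default: 1% of the sample count) and that lie within a 500-probe
window — defines the compacted matrix `V′` with `V′_b = Σ_{j∈bin b} V_j`.
NMF on `V′` with the compact `H` expanded back over the bins (each column
divided by its bin size) directly approximates the full `V`; at δ = 0 this
is exactly lossless. The discarding baseline ("standard"), which keeps one
representative per bin, is provided for comparison.

**Consensus and rank selection.** Each of `T` seeded restarts clusters
sample `i` to its largest `W` row entry; the sample × sample co-clustering
frequencies form a consensus matrix `C`, cut by average-linkage
hierarchical clustering on `1 − C`. The number of subgroups `k` is weighed
across measures per rank: the intra-cluster similarity `S(k)` (mean over
clusters of the average within-cluster `C_ij`, with median/max variants),
the cophenetic correlation, and the mean silhouette. Cluster–phenotype
association uses an exact conditional r × c Fisher test.

## Worked example

```python
import compactnmf as cn

ds = cn.generate(cn.default_spec(seed=0))          # 3 planted groups, 60 x 2,000 probes
F = cn.encode(ds.profiles, scheme="binary")
P = cn.build_partition(F, delta=cn.default_delta(F.n_samples), window=500)
Vc = cn.compact(F, P)
print(f"{F.n_features} feature columns -> {P.n_bins} bins (delta={P.delta})")
rep = cn.rank_report(Vc, ranks=[2, 3, 4, 5], T=50, base_seed=100, max_iter=500, tol=1e-6)
print(rep.table[["rank", "S_mean", "S_max", "cophenetic", "silhouette", "cluster_sizes"]]
      .round(3).to_string(index=False))
print("recommended rank:", rep.recommended_rank)
print("adjusted Rand vs planted groups:",
      round(cn.adjusted_rand(rep.clusterings[3].labels, ds.labels), 3))
```

prints

```
4000 feature columns -> 505 bins (delta=1)
 rank  S_mean  S_max  cophenetic  silhouette cluster_sizes
    2   0.851  0.973       0.992       0.766         35,25
    3   0.956  0.998       0.995       0.956      24,21,15
    4   0.814  0.933       0.994       0.841    24,20,13,3
    5   0.770  0.850       0.995       0.707  22,20,13,3,2
recommended rank: 3
adjusted Rand vs planted groups: 0.944
```

The 1%-rule compaction shrinks the matrix eightfold. `S_mean` peaks
sharply at rank 3, the planted group count; the rank-3 consensus clusters
recover the planted membership almost perfectly (adjusted Rand 0.944), and
the reported sizes match the planted 25/20/15 design up to the handful of
noise-dominated samples.

The same stages are available from the shell via the `compactnmf` CLI
(subcommands `simulate`, `encode`, `compact`, `factorize`, `consensus`,
`rank-scan`, `compare`, `fisher`); `rank-scan` and `compare` read a YAML
key-value config. See `compactnmf <cmd> --help`.

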