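# Methods

## Objective and optimizer

The factorization minimizes the generalized Kullback–Leibler divergence
`D(V ∥ WH) = Σ V log(V/WH) − V + WH` over non-negative `W`, `H`. This is
the Poisson maximum-likelihood objective, appropriate for count-like CN
severity encodings; it treats over- and under-prediction asymmetrically,
which is why gains and losses occupy separate non-negative channels rather
than a single signed feature. The optimizer is the classic multiplicative
update pair, applied `H`-first and then `W` against the fresh `H`, each
step guaranteed not to increase `D`. The problem is non-convex with many
local optima and is not identifiable, so no single run is trusted:
clustering decisions are always made from many seeded restarts.

Numerical conventions:

- `0 · log 0 = 0`; if the model puts exactly zero mass where `V > 0` the
  divergence is reported as `+inf` (a limit, not an error).
- `W`, `H` and every `(WH)` denominator are floored at `1e-12`.
  Multiplicative updates cannot revive an exact zero, so the floor keeps
  the iteration inside the strictly positive region where the convergence
  guarantee applies.
- Initialization is uniform on `(0, 1]` from an explicit integer seed
  (`numpy` PCG64); identical seeds give bitwise-identical factorizations.
- Convergence: stop when the relative per-iteration improvement of `D`
  falls below `tol` (default `1e-6`) or after `max_iter` (default 2000)
  steps. Consensus-scale experiments in the tests and the acceptance
  script use `max_iter=500, tol=1e-6`, which on the default synthetic
  cohort converges in a few dozen iterations; those are the problem sizes
  this package treats as its reference experiment
  (60 × 2,000 probes, 50 restarts, ranks 2–5).

## Encoding

Integer CN calls map per probe to a gain feature (0 / 1 for CN 3–4 / 2 for
CN > 4) and a loss feature (0 / 1 for CN 1 / 2 for CN 0); copy-neutral LOH
(LOH flag with CN 2) contributes 0.5 to the loss feature, reflecting a
milder loss-like lesion. Cohorts that only distinguish presence/absence
use the binary scheme (1 in the matching channel); LOH flags are then
ignored with a warning, since the fractional encoding only makes sense on
the severity scale. Loss-channel columns come first, then gain-channel
columns, each block in genomic order; the layout is recorded per column so
nothing downstream depends on it. Missing calls are rejected at load time
rather than imputed — profiles are assumed complete after upstream
segmentation, which is out of scope here.

## Compaction

Columns are binned by a greedy left-to-right pass within each
(channel, chromosome) block: the first unassigned column seeds a bin, and
every later unassigned column of the block joins it if its Hamming
distance **to the seed** is ≤ δ and its probe ordinal is within `window`
of the seed's. Choices made where the procedure was genuinely open:

- *Seed-based membership* (not all-members, not the running sum): O(n ·
  bins), deterministic, and bounds the within-bin diameter by 2δ.
- *Window on probe ordinals*, not base pairs, and anchored at the seed;
  default 500 probes. This keeps every genomic region represented in the
  compacted matrix instead of letting one bin swallow a whole chromosome
  of quiet probes.
- *No merging across channels or chromosomes*, even at distance 0, so
  every bin remains a genomically interpretable unit.
- δ defaults to `ceil(0.01 · m)` — columns may differ in at most 1% of
  samples (m = 533 gives δ = 6).

The compacted matrix sums each bin (`V′_b = Σ_{j∈b} V_j`); expanding a
compact `H` divides each bin column by its size. For bins of identical
columns the expanded full-matrix divergence equals the compacted
divergence *exactly* (per-column terms sum to the compacted term), so
δ = 0 compaction solves the full problem losslessly at a fraction of the
width. The discarding baseline keeps only each bin's seed column; its
full-matrix divergence is evaluated by replicating the representative's
`H` column to every member **without** division — the columns it dropped
were never seen by its optimizer, so each is modeled as a copy of the kept
one. That convention is one defensible reading of how a column-discarding
preprocessor should be scored against the full matrix; it is what the
`standard` mode of `divergence_ratio` measures. At δ = 0 both methods are
lossless up to column multiplicity and their ratios sit within about 1% of
1.0 either way (the optimization is local); under lossy compaction
(δ ≥ 1) the discarding baseline degrades several-fold while bin-summing
stays close to the lossless reference.

## Consensus clustering

Each restart labels sample `i` by the argmax of row `i` of `W` (ties to
the lowest component; an all-zero row is an error). The consensus matrix
holds co-clustering fractions over `T` restarts with consecutive seeds;
it is symmetric, has unit diagonal, and `T·C` is integral. The final cut
is average-linkage agglomerative clustering on `1 − C` (Ward presumes
Euclidean geometry; with a stable consensus matrix the choice of linkage
matters little, and it is configurable). Cluster ids are renumbered by
decreasing size, ties by first occurrence, for stable reporting. Restart
sufficiency is monitored by the stability curve: the RMS off-diagonal
difference between the first-`T` consensus matrix and the all-runs matrix
(a consecutive-prefix variant is also exposed); the curve ends at zero by
construction and flattens once additional restarts stop moving `C`.

## Rank selection

Per candidate rank the report tabulates the intra-cluster similarity
family — per cluster the mean of `C_ij` over unordered within-cluster
pairs (the diagonal excluded; singletons score 1 by convention, with an
option to exclude them since they can inflate the max aggregator) —
aggregated by mean, median and max, plus the cophenetic correlation of the
consensus dendrogram and the mean silhouette on `1 − C` (singleton samples
score 0). The *recommended* rank is the `S_mean` argmax, ties to the
smaller rank. This is a reporting default, not a verdict: the intended use
is to weigh all tabulated measures together. The cophenetic coefficient
was deliberately not used for the default recommendation — on clean
consensus matrices it is nearly flat across ranks (all values > 0.99) and
its argmax is driven by noise, whereas `S_mean` peaks decisively at the
planted rank in the recovery experiments; the max variant is most useful
for spotting one robust subgroup inside an otherwise weak rank.

## Association testing

Cluster–phenotype association uses the exact conditional test for r × c
contingency tables: all tables with the observed margins are enumerated
and the p-value sums the multivariate hypergeometric probabilities of
tables no more probable than the observed one (probability-ordering
two-sided convention, with a `1e-7` log-scale tie tolerance). Enumeration
is guarded by a table-count cap (default 5·10⁶); larger tables raise with
advice to use a Monte-Carlo approximation, which this package does not
implement. Survival association is likewise out of scope: the emitted
label tables are designed to feed standard survival tooling.

## Synthetic cohorts

The generator plants `k` subgroups, each defined by contiguous aberration
blocks (chromosome, probe range, channel, severity 1 or 2) carried by each
member independently with a per-block penetrance; background noise flips
single probes to a severity-1 aberration in a random direction,
independently at a fixed per-probe rate, with no spatial correlation — the
simplest null, so all spatial signal comes from the blocks. The default
design is a desk-scale rendition of a segmented SNP-array cohort: 60
samples in groups of 25/20/15, four chromosomes of 500 probes, two
120-probe lesions per group at penetrance 0.9, background rate 0.02.
Whole blocks toggling together create exactly the column redundancy the
compaction exploits. What the generator does **not** emulate: array
waviness and GC bias, segmentation artifacts, probe-density variation,
correlated noise, and subclonal (fractional) CN states — so passing
recovery tests demonstrate the pipeline's behavior under clean segmented
input, not robustness to raw-array pathology.

## Known limitations

- The greedy seed-based binning is order-dependent and makes no optimality
  claim; it is the pragmatic choice for matrices with heavy redundancy.
- Only the KL (Poisson) objective is implemented; Gaussian/Frobenius
  variants would need a different update rule and a re-derived compaction
  argument.
- The exact test is limited by enumeration size; moderate tables
  (e.g. 4 × 4 with totals in the hundreds) exceed the cap.
- Consensus clustering at `T` restarts costs `T` full factorizations;
  restarts are embarrassingly parallel, but the driver here runs them
  serially and in seed order so outputs are scheduling-independent.
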