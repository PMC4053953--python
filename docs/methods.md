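# Methods

## Signal model

Per-target read density (EMRC, reads/bp) is treated as proportional to
local copy number after bias removal. The pipeline never interprets a
single sample's density directly — single-sample depth poorly separates
copy-number states even after normalization — and instead works on the
log2 ratio of a test sample against a control (matched, or a pooled
reference built by summing raw per-target read counts across controls
and normalizing the pooled profile once).

### Read counting

A read is counted for the unique target containing its leftmost aligned
base. This makes counts additive and prevents double-counting across
abutting exons; an `overlap_any` mode counts a read once per overlapped
target for users who want coverage-style semantics. Default filters:
primary, mapped, MAPQ ≥ 1, duplicates excluded. Paired-end mates count
as two reads (the statistic is read density, not fragment density). All
filter settings are logged with each run so counts are reproducible.

### Median normalization

Three sequential passes (GC → mappability → size) of

    EMRC_i ← EMRC_i · m / m_X

with bin widths of 1 GC percent, 0.1 mappability, 10 bp size. Size bins
are capped: everything ≥ 1,000 bp shares one open-ended bin, because
large exons are rare and would otherwise sit in singleton bins that the
median cannot stabilize. Properties guaranteed per pass: every
non-empty bin's median equals the overall median afterwards; the overall
median is conserved; the map is scale-equivariant. A bin with zero
median cannot be rescaled — its targets are left unchanged and masked.
Empty bins contribute factor 1. The full three-step procedure is *not*
exactly idempotent in general (later passes perturb earlier bins'
medians slightly); it is exactly idempotent when the bias lives in a
single covariate, which is what the test suite asserts.

### Log2 ratio

Targets with control density below 0.1 reads/bp (configurable) are
masked — a ratio against near-zero coverage is noise. Optionally the
LOWESS trend of M = log2(test/control) against A = ½·log2(test·control)
is subtracted (fraction 0.3, 3 robustifying iterations), the standard
MA-style correction for intensity-dependent distortion; the unmasked
ratios are then re-centered to median 0 so the diploid state defines
zero. Caveat: LOWESS assumes CNVs are locally rare along the A axis. On
very small target sets (~100 targets) a clustered CNV can dominate its
A-neighborhood and be absorbed by the smoother; the end-to-end tests on
80-target fixtures therefore run with `lowess=False`, and users with
small panels should too.

## Segmentation: heterogeneous shifting level model

Observations x_i = m_i + ε_i, ε_i ~ N(0, σ_ε²); the latent level m_i
stays put between consecutive targets with probability 1 − η(d_i) and
jumps to a fresh level drawn from N(μ, σ_μ²) with probability

    η(d_i) = min(η_max, η₀^(D_Norm / d_i)),   η_max = 0.999.

η is increasing in the inter-target midpoint distance d_i: it vanishes
for tightly packed exons, equals η₀ at d_i = D_Norm, and saturates for
isolated targets. With the default η₀ = 0.5, D_Norm is exactly the
distance at which a level change becomes as likely as not — i.e. the
scale beyond which two targets are treated as effectively independent.
This default is deliberately large: at typical intra-gene spacings
(~1.5 kb) it still yields η ≈ 10⁻²⁰ (jumps inside genes are effectively
forbidden, which is what makes breakpoints land exactly on gene
boundaries), while across inter-gene gaps of ≥ 100 kb jumps are cheap
enough that an isolated altered gene of a few exons is detectable. A
small η₀ (e.g. 0.01) prices jump-and-return paths at 10–16 nats, more
than the total evidence a small CNV carries at realistic noise, and
makes the model insensitive regardless of the data.

### Inference

The level space is discretized: 21 evenly spaced levels spanning
μ ± 3σ_μ, blended with 13 empirical quantiles of the data
(0.1%…99.9%) so levels exist near rare extreme states that barely move
μ or σ_μ, with near-duplicates (within 0.05 σ_ε) collapsed. Transitions
are T_i(j→k) = (1−η(d_i))·1[j=k] + η(d_i)·p(k), with p(k) the
N(μ, σ_μ²) prior renormalized over the grid. The most probable path is
found by exact Viterbi in log space; because the jump term is
source-independent, each step costs O(L) (best off-diagonal source =
global best or runner-up). Ties break toward staying, so the decoded
path never contains a gratuitous breakpoint, and decoding is fully
deterministic. Segments are maximal runs of one decoded level; their
reported means are the *empirical* means of member targets, not the
quantized grid values, so calling sees unquantized evidence. Masked
targets are skipped, with distances measured midpoint-to-midpoint
between retained targets. A chromosome with a single usable target
yields one single-exon segment with a warning.

### Parameter estimation

From each chromosome's observed sequence: σ_ε = MAD(first
differences)/(√2·0.6745) — differencing cancels the piecewise mean, and
the robust scale ignores the few CNV-induced jumps; μ = 10%-trimmed
mean; σ_μ = √max(Var(x) − σ_ε², 0) floored at σ_ε, because a rare CNV
barely moves the total variance and a collapsed σ_μ would price real
copy-number levels out of the jump prior. σ_ε is additionally floored
at 0.01 — no real depth ratio is quieter than that (Poisson noise at
10,000× coverage is already ~0.014) — which keeps degenerate inputs
(identical values) stable. No per-sample re-estimation of η₀ or D_Norm
is attempted; both are exposed as configuration.

## Five-state calling

Segment means are modeled as a five-component mixture. Component means
are *fixed* at μ_s(c) = log2((c·CN_s + (1−c)·2)/2) for CN_s ∈
{0,1,2,3,4}; the homozygous-deletion mean at c = 1 (log2 0) is floored
at −5, far below any observable signal. Fixing the means is what keeps
five states identifiable from the handful of segments one exome yields.
Each component is truncated to the interval between midpoints of
adjacent state means, so supports partition the line and the call is a
nearest-mean rule softened by mixture weights and the shared σ. Weights
and σ are fitted by EM — responsibilities are hard under partitioned
supports, so the E-step is a bin assignment and the σ update is a
bounded 1-D likelihood maximization, accepted only when it improves the
likelihood (the log-likelihood sequence is non-decreasing by
construction). Segment log-likelihood contributions are weighted by
exon counts: a 100-exon segment is stronger evidence than a 2-exon one.
When cellularity is not supplied it is selected on the grid
0.10, 0.15, …, 1.00 by maximum likelihood. Exact posterior ties break
toward the lower copy number (conservative about amplification); calls
whose winning posterior falls below 0.5 are kept but flagged uncertain.
Note the posterior split at a support boundary is deliberately not
50/50: each truncated component renormalizes over its own support.

## Synthetic chromosomes

Each chromosome has exactly 1,000 exons, built from genes with exon
counts drawn U(5,100) (the last gene truncated to fit), intra-gene exon
gaps U(10,10000) bp, exon widths U(50,500) bp, and a fixed inter-gene
distance D. g altered genes of exactly N exons are placed at uniformly
chosen, never-adjacent gene slots; their exons carry an expected log2
ratio of −1 (one-copy) or log2(3/2) (three-copy), all others 0.
Per-exon noise is i.i.d. Gaussian with sd 0.5 by default — a pinned,
documented stand-in for the empirical noise that real log2-ratio
profiles inherit from sequencing depth. What this generator does *not*
emulate: correlated wave artifacts, GC-residual structure, the lower
variance of deleted states (available as `deleted_sd_scale`, default
off), or outlier exons. Passing benchmarks here demonstrates the
segmentation/calling machinery under known conditions, not performance
on any particular capture platform.

Benchmarks score a non-normal call as a true positive when it overlaps
≥ 50% of a planted region's exons *and* matches its direction; as a
false positive when it overlaps no planted region; calls with
intermediate overlap fit neither definition and are reported separately
as "partial". Breakpoint accuracy is |predicted − true| in exons per
true-positive boundary, "exact" meaning distance 0.

## Problem sizes and tolerances

The acceptance benchmark (`scripts/acceptance.py` and
`tests/test_acceptance.py`) uses 200 chromosomes per condition — enough
for a binomial standard error of ~1.5% on a 95% rate — at the
conditions: (one-copy, 10 exons, D = 100 kb), (three-copy, 20, 100 kb),
(one-copy, 3, 1 Mb), (three-copy, 10, 1 Mb) at noise sd 0.5, and
breakpoint exactness for (one-copy, 10, 1 Mb) at sd 0.2, all with
D_Norm = 10⁵. The 3-exon cell is intrinsically marginal under isotropic
sd-0.5 noise: even a perfect segmenter places a 3-exon mean below the
−0.5 calling boundary only Φ(0.5/(0.5/√3)) ≈ 95.8% of the time, so
observed rates sit at ~0.94–0.96 depending on the realization. The
Viterbi implementation is checked against exhaustive path enumeration
and an independent dense max-product recursion on 1,000 random small
instances (≤ 12 exons, ≤ 6 levels) to 10⁻⁸ absolute log-probability.

## Known limitations

- No allele-fraction (BAF) integration; heterozygous and homozygous
  events are separated purely by shift magnitude.
- One global cellularity parameter; no multi-subclone deconvolution.
- Chromosomes are segmented independently; no cross-chromosome shrinkage.
- The pooled reference weights controls by read count, so one deeply
  sequenced control dominates the pool.
- LOWESS correction is unreliable below a few hundred targets (above).
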