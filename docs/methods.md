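# Methods

## Generative model

Reads are modelled as independent draws from a multinomial density
π = (π₁, …, π_M) over the M positions of a genome grid (default 1-bp bins;
chromosomes occupy contiguous index ranges). For read *i* the aligner
reports a candidate set R_i; the true origin is latent and assumed to be one
of the reported candidates, with equal alignment fidelity at each (the
aligner has already filtered by mismatch count, so within-set quality
differences are ignored). Uni-reads (|R_i| = 1) are fully observed and act
as the local count evidence; multi-reads (1 < |R_i| ≤ 99) are the
allocation targets.

Chromatin accessibility enters through a Dirichlet prior on π with
parameters γ_j = S_j + 1. The offset of one keeps every γ_j ≥ 1, so the
M-step numerator can never go negative and the MAP estimate stays in the
simplex interior wherever data or prior places mass. The pseudo-counts
follow a log-linear spline regression on the per-position DNase count x_j,
optionally extended with trinary histone codes:

    S_j = exp[β₀ + β₁·SP(x_j) + β₂·h_j]

## Covariate construction

* **DNase track** — reads from a pre-allocated DNase-seq sample (every read
  kept only if its allocation probability is ≥ 0.9; uni-reads always pass)
  are extended to the average library size (default 200 bp) from their 5′
  ends in strand direction, truncated at chromosome boundaries; x_j is the
  number of covering fragments. The pre-allocation can be supplied as a
  table or computed by this package's own uniform-prior allocator.
* **Histone codes** — each histone ChIP-seq count track is reduced to
  {0, 1, 2} at its own empirical 90th and 99th nearest-rank percentiles
  (computed over all M positions, zeros included; boundary equality resolves
  to the lower class, so a value exactly at the 90th percentile codes 0).
  The trinary reduction reflects that histone state is closer to
  modified/unmodified than to a continuous scale, with the middle class
  capturing moderate enrichment.
* **ChIP uni-read counts** — the regression response is the number of
  uni-read 5′ starts per position (no extension), since π is a density of
  read starts.

## Prior estimation

Fitting genome-wide would be dominated by the ~99% of positions with
near-zero accessibility, so positions are aggregated: one group per
distinct (pooled DNase count, histone pattern), with the mean uni-read
count S̄, the group size, and the mean covariate value x_rep per group.
Two pooling rules stabilise the extremes: counts {0, 1, 2} form a single
low-count group, and counts above the 99.95th percentile of the *positive*
count distribution form a single high-count group. Pooled groups are
represented by their mean x and receive the pooled prediction when the
model is evaluated per position.

The fit is weighted least squares of log(S̄ + ε) on an intercept,
a degree-1 B-spline basis in x_rep, and histone dummies (codes 1 and 2
versus baseline 0, two columns per track), with group sizes as weights.
Least squares on the log of a group *mean* is preferred to a Poisson fit
because the response is already an average, and the group size is its
natural precision weight. Design choices:

* **Knots** at the 90/99/99.9th nearest-rank percentiles of the distinct
  aggregated values, with boundary knots at the observed extremes.
  Percentiles are taken over the aggregated values rather than weighted by
  genomic footprint: with zero-inflated accessibility the weighted
  distribution is all low-count mass and would collapse every knot onto the
  pooled class, leaving the informative upper tail unmodelled. Predictions
  extrapolate flat beyond the trained range (a counter records clamped
  positions). A rank-deficient design retries with fewer knots; a
  single-row table reduces to an intercept.
* **ε** (the log guard) defaults to "auto": one tenth of the size-weighted
  mean count, capped at 0.1 and floored at 10⁻⁴. Deep datasets therefore
  use the conventional 0.1, while shallow data get a guard that does not
  dominate the low-coverage end of the curve. Predictions are
  exp(linear predictor) and hence estimate the ε-offset mean; the offset is
  negligible wherever counts are well above ε.
* **Histone selection** — a group lasso with one penalty group per histone
  track (spline columns unpenalized), solved by FISTA with group
  soft-thresholding over a 30-point log-spaced λ grid (λ_max derived from
  the DNase-only residuals). λ is chosen by BIC on an unpenalized refit of
  each selected set, and the returned model is that refit. BIC is used
  because the aggregated rows are few and selection consistency matters
  more than predictive tuning.

## EMS estimation of π

With the prior fixed (joint estimation of β and π would require numerical
optimisation inside every M-step), the allocator iterates

* E-step: z_ij = π_j / Σ_{j′∈R_i} π_j′,
* M-step: μ_j = (Σ_i z_ij + S_j) / (N + Σ_j S_j),
* S-step: π_j = mean of μ over [j−w, j+w] within the chromosome, then a
  global renormalization.

Numerical and structural choices:

* **Sparsity.** π is materialized on merged intervals spanning every
  candidate position ± 2w; outside, positions carry their prior-only mass
  S_j/(N + ΣS_j), accounted for analytically via the prior's exact total
  mass (computed class-wise, never by a dense genome loop). Smoothed values
  are computed where they can differ from that baseline (candidates ± w);
  elsewhere the unsmoothed baseline stands in. This approximation affects
  only the global normalizer — within-read ratios, and hence every z — are
  exact, and at w = 0 the whole computation is exact.
* **Smoothing windows truncate** at chromosome ends with the divisor shrunk
  to the actual window size (a truncated mean), so a constant density is
  exactly invariant; smoothing never crosses chromosome boundaries. The
  default half-window makes 2w+1 equal the average library size (200 bp at
  1-bp bins), matching the fragment-extension scale.
* **Initialization**: π⁰ ∝ uni-read counts + S + 1/M; the 1/M floor keeps
  the first E-step defined everywhere.
* **Convergence** on max_i max_j |Δz_ij| < 10⁻⁶ (the responsibilities are
  the deliverable), capped at 500 iterations; both configurable. The final
  z always comes from the final π.
* **Determinism**: the engine contains no randomness; identical inputs give
  bit-identical allocations. Tie-breaking at export time uses a
  caller-supplied seed recorded in the run manifest.
* The uniform-prior baseline (S ≡ 0, γ ≡ 1) is the CSEM special case and
  is exposed as `csem_allocate` / `--uniform-prior`.

## Thresholds

* DNase pre-allocation filter: keep at probability **≥ 0.9** (inclusive).
* BED export: a multi-read is written at its best position only if that
  probability is **> 0.5** (strict; an inclusive flag exists because the
  boundary convention is ambiguous in practice — at most one candidate can
  clear 0.5 either way). Uni-reads are always written. The alternative
  "argmax" mode writes every read at its best position with seeded random
  tie-breaking, the convention used when scoring simulations.

## Synthetic benchmark

The generator builds the conditions the allocator is meant to face, with
everything known:

* one 1-Mb chromosome; ten 1-kb duplication pairs placed in disjoint
  blocks (source and copy);
* 25 binding events of 200 bp: one centred in each source copy (the copy
  partner keeps background accessibility), the rest on non-duplicated
  ground; DNase rates are triangular peaks with log-uniform summit heights
  in [10, 30] around the default summit rate of 20, over a background rate
  of 0.2 — summit strengths and within-peak gradients mimic the broad
  intensity range of real hypersensitive sites and keep every accessibility
  level populated;
* per-position DNase counts are Poisson around those rates, and the read
  density is π*_j ∝ exp(β₀ + β₁·x_j) with β₁ = 0.2, so the assumed
  ChIP-versus-DNase structure holds by construction;
* 10⁵ reads drawn i.i.d. from π* (a medium depth; 10⁴ and 10⁶ are the
  low/high settings); any read starting inside a duplicated interval
  deterministically gains the homologous coordinate as a second candidate
  (the confusion rule), and its true origin is recorded.

The confusion rule replaces sequence-level re-alignment: it is exact,
fast, and controllable. What the generator does **not** emulate: partial
homology (every duplicated base is perfectly ambiguous), >2-way
repeats, mapping errors and quality variation, fragment-length variation,
and DNase footprint structure within peaks. Consequently, passing
benchmarks show that the estimator recovers the model it assumes under
realistic ambiguity patterns — not that real segmental duplications behave
this well. A sequence-emitting mode (FASTA/FASTQ) exists for running a
real aligner, but the tests do not depend on it.

On this benchmark uni-read evidence is absent inside duplications, so the
uniform-prior baseline sits on a neutral EM plateau (its accuracy hovers
around chance, decided by slow diffusion from the interval flanks, and
typically exhausts the iteration cap); the DNase prior breaks the symmetry
and lifts multi-read accuracy to ~0.82–0.89 across seeds.

## Problem sizes in the test suite

Oracle-equivalence tests compare the sparse engine against an independent
dense loop implementation on 200 random instances of ≤ 10 reads and ≤ 8
positions (exact to 10⁻⁸); the paired benchmark uses 20 replicates at the
default scale (10⁵ reads, 1 Mb); prior recovery uses the aggregated-table
fixture (x = 3..200) and three generated instances, where the fitted curve
is compared on covariate classes with at least 20 member positions —
smaller classes' sample means are noisier than the 10% band being checked.

## Known limitations

* Single-end reads only; h_ij beyond the 0/1 compatibility indicator
  (e.g. mapping-quality weights) is not modelled.
* β and π are estimated in two stages; the prior is not updated from the
  final allocation.
* The group lasso's BIC uses the aggregated rows as its sample size; with
  very few rows the selection can be liberal (an independent histone
  occasionally survives alongside a truly informative one).
* The S-step is a fixed-width moving average; no adaptive bandwidth.
* Genome-scale inputs are limited by the dense per-chromosome covariate
  tracks (int64 per position), fine up to tens of megabases per process at
  default settings.
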