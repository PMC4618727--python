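# permseq

Prior-enhanced allocation of multi-mapping ChIP-seq reads using
chromatin-accessibility (DNase-seq) derived Dirichlet priors.

## The problem

A sizeable fraction (5–30%) of ChIP-seq reads align equally well to several
genomic positions — *multi-reads* — mostly because of segmental duplications
and other near-identical repeats. Discarding them blinds peak calling to
regulatory activity inside repetitive regions. Allocators that use only the
local counts of uniquely mapping reads (*uni-reads*) fail exactly where they
are needed most: when the candidate positions have similar local coverage.
`permseq` breaks such ties with an independent data source — DNase-seq
accessibility, optionally sharpened by histone-modification ChIP-seq.

## The model

Read origins are multinomial draws from a density π = (π₁, …, π_M) over the
genome. For read *i* with candidate set R_i we observe only the alignment
indicators; the true origin is latent. Accessibility informs a Dirichlet
prior on π with parameters γ_j = S_j + 1, where the pseudo-counts follow a
log-linear B-spline regression on the DNase count x_j (and trinary histone
codes h_j):

    S_j = exp[ β₀ + β₁·SP(x_j) + β₂·h_j ]

SP(·) is a piecewise-linear spline with interior knots at the 90/99/99.9th
percentiles of the aggregated counts. β is fit by size-weighted least
squares of log(S̄ + ε) on a table that aggregates uni-read counts over
positions sharing the same (pooled) DNase count and histone pattern; with
several histone tracks, a group lasso (one group per track, BIC-chosen
penalty) decides which tracks enter. The posterior is maximised by an
**EMS** iteration:

* **E**: z_ij = π_j / Σ_{j′∈R_i} π_j′ (allocation probabilities),
* **M**: μ_j = (Σ_i z_ij + S_j) / (N + Σ_j S_j),
* **S**: π = moving average of μ (half-window w, 2w+1 ≈ library size),
  renormalized.

Setting S_j ≡ 0 recovers the uniform-prior baseline (CSEM), exposed as its
own entry point for comparisons.

## Worked example

```bash
# 1. simulate a 1-Mb toy genome with duplicated segments and known truth
permseq simulate --out sim/ --seed 4

# 2. run the full pipeline: covariates -> prior -> EMS -> exports
cat > pipeline.yaml <<EOF
chip: sim/reads.bowtie
dnase: sim/dnase_counts.bedgraph
chrom_table: sim/chroms.tsv
out_dir: run/
seed: 1
EOF
permseq pipeline --config pipeline.yaml

# 3. score the allocations against the recorded truth
permseq score --table run/allocations.tsv --truth sim/truth.tsv
```

The simulate step prints

    instance written to sim (100000 reads, 7.9% multi)

and the final scoring step prints (this exact output for these seeds):

```json
{
 "n_multi": 7860,
 "accuracy_multi": 0.8861323155216285
}
```

meaning 7,860 reads aligned ambiguously to both copies of a duplicated
segment and 88.6% of them were assigned to their true origin. Re-running
with `permseq pipeline --config pipeline.yaml --uniform-prior` drops the
accuracy to roughly 50–60%: local counts cannot distinguish the two copies,
while the DNase prior can. `run/allocations.tsv` holds one row per
(read, candidate) with its allocation probability; `run/allocated.bed`
keeps each multi-read at its best position when that probability exceeds
0.5 (the threshold used ahead of peak calling); `run/manifest.json` records
every parameter and the convergence state of the run.

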