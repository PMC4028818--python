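# Methods

## The model

Gene expression is modeled as a bipartite linear system on log-scale data:

    X = A S + Γ

with `X` the N×K expression matrix (N genes, K samples), `A` the N×M matrix
of regulation strengths whose sparsity pattern is the true TF→gene binding,
`S` the M×K latent matrix of TF activities, and `Γ` additive Gaussian
noise.  Only *foreground* genes (true TF targets) follow the model;
*background* genes are expression noise with matched variance.  The
observed motif-binding matrix `W` is a binary, contaminated estimate of
`A`'s support: spurious motif matches (false positives) connect both
foreground and background genes to TFs that do not regulate them.

The package identifies, from `X` and `W` alone: (i) co-regulated gene
modules, (ii) the TFs driving each module, and (iii) which candidate
targets of those TFs are genuine.

## Step one: motif-guided affinity propagation (mAPC)

Genes are clustered with the blended similarity

    s(i,j) = −(1−λ)·‖x_i − x_j‖² + λ·s_reg(i,j),
    s_reg(i,j) = Σ_m w(i,m)·w(j,m),

where `s_reg` counts TFs with candidate sites in both promoters.  λ ∈
[0,1] trades co-expression against co-regulation evidence; λ=0 is
classical affinity propagation on expression, λ=1 clusters on binding
alone.  Because the two terms live on unrelated scales (squared distances
grow with K; shared-motif counts are small integers), each term is divided
by the standard deviation of its off-diagonal entries before weighting
(`normalize=True`, default); the literal unnormalized sum is available.
Under high false-positive contamination the binding term degrades and λ
should be lowered toward expression — the trade-off the similarity was
designed to expose.

Affinity propagation itself is the standard responsibility/availability
message-passing scheme with damping (default 0.9, max 1000 iterations,
converged when the exemplar set is stable for 50).  It is deterministic;
an optional seeded symmetric jitter (`tie_noise`) exists for exactly tied
similarities, off by default.  The shared diagonal *preference* controls
the number of clusters: `"median"` (package default, moderate cluster
counts), `"min"`, and `"low"` = min − 4·(max−min), the regime used by the
benchmark study where a handful of large modules is expected.  Preference
is the one knob a user should expect to adjust per dataset.

## TF identification

Each cluster is tested for enrichment of each TF's candidate targets with
the upper-tail hypergeometric probability

    p = Σ_{i=Nb}^{min(NB,Nc)} C(NB,i)·C(N−NB, Nc−i) / C(N,Nc)

(N genes in the population, NB bound by the TF, Nc in the cluster, Nb
bound cluster genes), computed through the survival function rather than
the literal factorial sum.  Raw p-values are reported with a configurable
threshold (default 0.05); no multiple-testing correction is applied by
default, with Benjamini–Hochberg available to callers that want it.
P-values convert to bounded scores Φ⁻¹(1−p), capped at 4; the cap tames
the infinities of essentially-zero p-values.  A TF "identified at
confidence level 0.9" means score ≥ Φ⁻¹(0.95) ≈ 1.645, i.e. enrichment at
p ≤ 0.05 — the two-sided reading of the confidence level, chosen because
the matching threshold (1.65) is the field's customary cut-off.

## Step two: Gibbs sampling on the outlier-sum statistic (GibbsOS)

Within a cluster, the expression of one true target per TF ("seed" genes,
Θ = [θ_1..θ_M]) spans the same space as the TF activities, so any other
true target y regresses well on the seed matrix F (K×M, plus intercept):

    β̂ = (FᵀF)⁻¹Fᵀy,   MSE = (yᵀy − yᵀF(FᵀF)⁻¹Fᵀy)/(K−M−1),
    t_m = β̂_m / sqrt(MSE·C_mm).

For a tentative seed θ_j = candidate i, every other candidate k of TF j is
regressed on F and the t-statistics of TF j's coefficient are summed over
those exceeding the two-sided Student-t threshold:

    OS(θ_j=i) = Σ_{k≠i} |t_jk| · 1{|t_jk| ≥ t_{α/2, K−M−1}}.

The absolute-value convention is the default because regulation strengths
may be negative; the literal one-sided form is available (`signed=True`).
Normalizing OS over TF j's candidates gives the conditional distribution
of θ_j given the other seeds; a systematic-sweep Gibbs chain samples every
TF per iteration, and post-burn-in seed frequencies estimate each
candidate's marginal probability of being a true target.  Genes rank by
their maximum frequency over TFs.

Numerical choices: perfect fits (MSE=0) report |t| = 1e6 instead of
infinity, preserving ranking without NaNs; an all-zero OS vector falls
back to uniform weights so the chain stays irreducible; a rank-deficient
FᵀF (duplicate seeds across TFs) uses the pseudo-inverse and flags the
fit.  Defaults: α = 0.05, 500 sweeps, burn-in 100, fixed TF sweep order,
seeded initialization uniform over each candidate set.

The conditional for TF j is computed by residualizing all candidates of
TF j against the intercept and the other TFs' seeds (one least-squares
solve), then forming the Gram matrix of residuals: the t-statistic of the
pair (seed i, target k) is G_ik·sqrt(dof)/sqrt(n_i·n_k − G_ik²).  This is
the Frisch–Waugh–Lovell identity, algebraically equal to fitting each
(i,k) regression separately; the test suite asserts agreement with the
literal per-pair route to 1e-8.

### Regression capacity and TF batching

The seed regression needs K > M + 2.  The benchmark, however, asks for
runs with M = 80 TFs at K = 5..45 samples — far past capacity.  When the
TF set exceeds K−2, the sampler partitions it (seeded, near-equal) into
batches of at most K−2 TFs, runs an independent chain per batch, and
concatenates the per-TF frequencies.  Each batch ignores confounding from
TFs outside it, which degrades the pool-wide sampler exactly where the
clustered variant — whose per-cluster TF sets are small — is unaffected;
this is the mechanism behind the small-sample advantage of the two-step
method in the study.  `regress` itself rejects K ≤ M+1 rather than
silently pseudo-inverting an underdetermined system.

## The synthetic benchmark

`simulate` generates datasets with known truth.  Defaults (the study
conditions): 100 foreground genes in 2 modules of 50, 200 background
genes, 80 TFs, 20 samples, SNR 5 dB, FP ratio 1.0.  Structure:

- **TF partition.** Each foreground module owns a disjoint TF set sized
  proportionally to its gene count (13 of 80 by default); background
  pseudo-modules split the remaining TFs (27 each).  Every TF therefore
  has targets; there are no "dead" columns for false positives to turn
  into give-away pools.
- **Binding.** Foreground genes bind 5 TFs of their module, uniformly
  without replacement.  Background genes carry a decoy binding pattern
  mirroring the foreground scheme on their own TFs — motif matches are
  real sequence features regardless of regulation — with degree 6, one
  more than foreground, so decoy candidate pools are at least as large as
  true ones and sampling frequencies of unregulated genes stay
  conservative.
- **False positives.** round(fp_ratio × TP) extra 1-entries, with TP the
  count of true connections in foreground rows, placed uniformly on zero
  cells of *all* rows: spurious motif matches hit unregulated genes too,
  which is precisely what lets background genes be falsely clustered with
  true targets and gives the second step something to remove.  A
  `fp_rows="foreground"` switch restricts injection to foreground rows.
- **Expression.** TF activities iid N(0,1); regulation strengths on the
  true support drawn U(0.5, 1.5) — positive, unit-mean activation
  strengths, so co-regulated genes are positively correlated (with signed
  zero-mean strengths co-regulated genes would be uncorrelated in
  expectation and co-expression clustering would be impossible by
  construction); a `strength_dist="normal"` option keeps the signed
  variant.  Noise is scaled so the realized foreground SNR equals the
  requested value exactly; background rows are Gaussian scaled to the
  empirical foreground variance.

What the generator does *not* emulate: real promoter sequence (binding is
abstract), TF–TF interactions, heteroscedastic per-gene noise, and
overlapping modules (a gene belongs to exactly one).  Results on this
benchmark therefore speak to the method's behavior under modular
structure with calibrated contamination, not to performance on any real
expression compendium.

## Evaluation and the study runner

`adjusted_rand_index` implements the chance-corrected pair-counting form
directly (identical partitions define ARI = 1 even when the correction
term degenerates).  `roc_auc` is the Mann–Whitney normalization with
midrank ties.  The study runner sweeps the benchmark grid — FP ratios
0.5/1.0/1.5 at 5 dB, SNR 0/5/10 dB at FP 1.0, sample sizes 5..45 at
5 dB / FP 0.5 — with five seeded repetitions per cell, comparing mAPC
against plain APC, k-means and Ward hierarchical clustering (library
implementations, k = number of truth classes), and the two-step method
against pool-wide GibbsOS.  Clusters are matched to modules by majority
overlap of foreground genes.  The ground-truth partition for ARI places
each foreground module in its own class and all background genes in one
class.  The test suite runs this study at 200 Gibbs sweeps per chain and
the acceptance script at 400 (its `--sweeps` flag changes the scale).

## Pipeline and bootstrap

For two-group designs, genes are preselected by per-gene Welch t-test
(pooled-variance optional) at p < 0.05 and split by sign of the mean
difference into up-/down-regulated sets, which are analyzed separately.
Bootstrap confidence: resample samples with replacement (stratified
within groups, preserving the group sizes the t-test needs), rerun
preselection and the full two-step pipeline per resample, and report per
TF the fraction of resamples in which its best cluster enrichment score
reaches the confidence threshold (default 100 resamples, level 0.9).
Degenerate resamples (an all-constant group) are redrawn.

## Known limitations

- The frequency score is relative to a candidate pool's size, so AUC
  comparisons across pools assume roughly balanced pools; the default
  generator balances them deliberately.
- With exactly symmetric similarities affinity propagation can oscillate;
  use `tie_noise` for pathological inputs.
- The full-partition ARI of the benchmark caps below 1 whenever the
  clustering resolves the background's decoy modularity (the truth calls
  all background one class); the per-foreground-module ARI
  (`ari_mapc_fg`) is reported alongside.
- Batched sampling treats TF batches independently; cross-batch
  collinearity of seeds is not modeled.
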