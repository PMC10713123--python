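# Methods

## Model

Let y_i ∈ {0, 1} be the group label of subject i and x_i its P-vector of
expression values, standardized per gene *within* each group. Under a
Gaussian graphical model per group, x | y = k ~ MVN(μ_k, Σ_k), and the
log-odds of group membership is a quadratic form in x whose interaction-term
coefficient matrix is B = −(Ω₁ − Ω₀)/2 with Ω_k = Σ_k⁻¹. Pairs where the two
precision matrices differ — the differential network — are therefore exactly
the pairs with nonzero interaction coefficients in the logistic regression

    logit P(y_i = 1) = α₀ + Σ_{(j,k) ∈ S_R} β_jk · x_ij · x_ik .

Main effects are omitted: within-group standardization forces both group
means to zero, under which the main-effect vector ξᵀ = μ₁ᵀΩ₁ − μ₀ᵀΩ₀ of the
log-odds decomposition vanishes. The model is fitted only on the screened
pair set S_R (stage 1 below).

Priors:

* β_jk | γ_jk ~ γ_jk·ψ₁(β) + (1 − γ_jk)·ψ₀(β), with Laplace components
  ψ_m(β) = (τ_m/2)·exp(−τ_m|β|) — the spike-and-slab Lasso;
* γ_jk ~ Bernoulli(θ);
* α₀ ~ N(0, σ²).

The posterior probability P(γ_jk = 1 | data) measures the uncertainty of the
differential edge (j, k); the posterior mean of β_jk is its intensity, whose
sign follows the label mapping (the lexicographically smaller class is
group 0).

### Hyperparameters

| parameter | default | meaning |
|---|---|---|
| τ₀ | 20 | spike scale; prior SD of a null β is √2/20 ≈ 0.07 |
| τ₁ | 2 | slab scale; prior SD of a real β is √2/2 ≈ 0.71 |
| θ | 0.7 | prior edge-inclusion probability — above ½ because every pair in the model already survived the correlation screen |
| σ | 10 | intercept prior SD; vague but proper. No principled value presents itself for a balanced two-group design, where α₀ ≈ 0 anyway |
| threshold | 0.5 | posterior probability at which an edge is declared; higher cutoffs give nested subnets |

## Stage 1: screening

With P genes there are φ = P(P−1)/2 candidate pairs; most are not
differential. The screen computes per-group sample Pearson correlation
matrices, forms Δ_jk = ρ̂_jk1 − ρ̂_jk0, and keeps the S pairs with largest
|Δ_jk|. Raw Δ is ranked (no Fisher transform). Ties are broken
lexicographically by (j, k) so the screen is deterministic. S can be chosen
as:

* `n_ratio` — the integer closest to N/P (round half up), N the pooled
  sample size;
* `sparsity_fraction` — fraction × φ (round half up), typically 0.05–0.10,
  reflecting how sparse single networks in public pathway databases are;
* `explicit` — a user-supplied S.

Correlations are invariant to the within-group standardization, so screening
before or after standardizing is equivalent; both groups need ≥ 3 subjects.

## Stage 2: MCMC

The sampler is slice-within-Gibbs:

* **γ_jk | β_jk** is conjugate Bernoulli with log-odds
  log(θ/(1−θ)) + log(τ₁/τ₀) + (τ₀ − τ₁)|β_jk| — updated exactly.
* **α₀ | rest** and each **β_jk | rest** are updated by univariate slice
  sampling (stepping out + shrinkage, initial width 1, Neal-style), on the
  log of likelihood × prior. The linear predictor is cached and updated in
  O(N) per coordinate.

Any kernel with the correct stationary distribution would do; this one was
chosen because every conditional is log-concave or discrete, it needs no
tuning, and it has no rejection steps. Its correctness is verified in the
test suite against an independent oracle that enumerates γ configurations
and integrates (α₀, β) numerically on kink-aware grids: for S ∈ {1, 2},
N ≤ 30, MCMC inclusion probabilities agree with quadrature within 0.02 (in
practice within ~0.003).

Defaults: 2 chains × 6000 iterations, 3000 burn-in, no thinning, fixed seed;
chains run on independent substreams spawned from the seed, so results are
bit-reproducible. Convergence is flagged (not fatal) when the split-chain
R-hat of any parameter exceeds 1.1; R-hat and effective sample sizes are
computed with ArviZ. With zero observations the draws target the prior,
which is how prior recovery is checked; because γ draws autocorrelate
(effective sample fraction ≈ 0.25), Monte-Carlo standard errors for such
checks use the effective, not nominal, draw count.

## Differential network construction

Edges with inclusion probability ≥ threshold form the D-Net, sorted by
probability (ties: |intensity|, then name). `subnet` re-thresholds upward
(nested by construction), `rank_edges` returns the full probability-ordered
candidate list for prioritization, `hub_degrees` counts incident edges per
node (no numeric "hub" cutoff is imposed — degrees are reported and the
label left to the analyst). Graphs are undirected; exports are edge-list TSV
and GraphML with probability/intensity edge attributes. `sparsity` reports
100·E/φ rounded half-up to one decimal, the convention used in tabulations
of network sparsity.

## Classification

Each retained draw (α₀, β) maps a subject's interaction products through the
inverse logit to a draw of P(y = 1 | x); the set over draws is the subject's
posterior-predictive distribution, its mean the point probability, and the
label is mean ≥ cutoff (default 0.5). Test subjects are standardized with
the **pooled** training mean/SD per gene: the group-specific statistics used
in training would require the unknown label, so using them would leak it.
This makes in-sample "fitted values" (pooled-standardized) differ slightly
from the training transform — a deliberate, documented asymmetry.

## Simulator

Data are drawn i.i.d. MVN(0, Ω⁻¹) per group via the precision Cholesky
factor. Precision matrices are built from signed partial-correlation target
matrices: unit diagonal, ω_jk = −ρ_jk on edges, zero elsewhere, so realized
partial correlations −ω_jk/√(ω_jj·ω_kk) equal their targets exactly whenever
the raw matrix is already positive definite. When it is not, |λ_min| + 0.05
is added to the diagonal and the matrix rescaled to unit diagonal — a
deterministic adjustment that shrinks all partial correlations by the common
factor 1/(1 + shift); the construction record stores the shift and the
realized values.

Shipped scenarios:

* **structural** — a synthetic 32-node pathway-like graph (42 edges, one
  degree-17 hub named STAT1, shipped as a plain TSV edge list imitating
  JAK-STAT topology; hand-built, not database-derived) with all partial
  correlations 0.2; group 0 lacks the hub's 17 edges. Both precisions are PD
  unadjusted, so the true differential intensity is exactly 0.2 per edge.
* **sign_flip** — same structure in both groups, but the hub's 17 edges
  carry precision targets +0.11 vs −0.11 (differential intensity exactly
  0.22); remaining edges 0.2 in both.
* **ar** — group 0 is an AR(1) chain (first-order partial correlation 0.3),
  group 1 an AR(2) band (0.3 and 0.22). The AR(1) matrix is PD unadjusted at
  all shipped sizes; the AR(2) band is not PD as specified (its symbol
  1 − 0.6·cos t − 0.44·cos 2t dips below zero) and receives the diagonal
  shift, so its realized partial correlations are ≈ 0.275/0.202. The true
  D-Net is extracted with tolerance 0.05, which keeps exactly the P−2
  second-order pairs (first-order entries differ by only ≈ 0.025 between
  groups after the shift).

`run_scenario` drives simulate → standardize → screen → fit → threshold →
score per replicate, spawning per-replicate seeds from one scenario seed,
and aggregates mean and standard error of TP/FP/FN/TN/SEN/SPE/FDR/MCC/F1.
It also records, per replicate, a one-sided Mann-Whitney p-value that true
edges out-rank null pairs by inclusion probability (unscreened pairs enter
at probability 0).

### What the simulator does and does not emulate

It reproduces the conditional-dependence structure that defines a D-Net and
the group sizes typical of expression studies (default n = 250 per group).
It does **not** emulate heavy-tailed or count-distributed expression,
batch/library-size artifacts, mean shifts between groups (group means are
identically zero), or correlated sampling of subjects. Passing tests
therefore demonstrate correctness of the inferential machinery under the
generative model it assumes, not robustness to real-data violations of
multivariate normality.

## Evaluation

`recovery_metrics` scores edge sets over the full universe of φ pairs, so
pairs lost at screening count as false negatives. F1 = 2TP/(2TP+FP+FN).
Zero-denominator conventions (flagged in the report): FDR = 0 when nothing
is called; SEN = 0 when there are no true edges (null scenarios); MCC = 0
when any confusion-matrix marginal vanishes.

## Numerical conventions and degenerate inputs

* Sample SDs use the n−1 denominator throughout (correlations unaffected).
* Zero-variance genes within a group are a hard error naming the gene —
  never silently dropped or imputed; missing values are a hard error.
* "Integer closest to" uses round-half-up (⌊x + 0.5⌋).
* Bernoulli log-likelihoods use `logaddexp` for stability; an empty dataset
  contributes zero log-likelihood (the sampler then targets the prior).
* Correlation matrices are clipped to [−1, 1] after `corrcoef` to absorb
  roundoff; diagonals are set to exactly 1.
* PD is certified by smallest eigenvalue > 1e−8.
* Labels: the lexicographically smaller original class becomes group 0; the
  mapping is recorded so the signs of Δ and β stay interpretable.

## Problem sizes in the shipped checks

The test suite runs the full pathway-scale recovery at P = 32, n = 250 per
group with 5 signal and 3 null replicates, single-chain 4000-iteration fits
(about a minute total); the sampler-vs-quadrature checks use N ≤ 30 and
S ≤ 2, where the quadrature oracle is accurate to ~1e−4; classification uses
150 training and 25 test subjects per group. These sizes were chosen so the
whole suite completes in a few minutes while each check still exercises the
regime it is about (e.g. n/P ≈ 15 as in the screening heuristic).

## Limitations

* MCMC over interaction terms does not scale to thousands of screened
  pairs; the intended regime is pathway-scale panels (P ≈ 30–100, S up to a
  few hundred).
* The method infers *differences* in conditional dependence; it does not
  reconstruct each group-specific network, and graphs are undirected.
* Inclusion probabilities are calibrated under the model; with θ = 0.7 the
  prior favors inclusion, so screened-but-null pairs retain non-trivial
  posterior probability when the data are weak (visible as false positives
  at threshold 0.5 in null simulations).
* The shipped pathway fixture is a synthetic stand-in: topology plausible,
  biology not curated.
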