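# Methods

## Model

Let x_1, …, x_N ∈ R^g be log-transformed bulk expression profiles for g
genes and N samples, with grand mean x̄ = (1/N) Σ_i x_i. Two
assumptions define the model:

1. **Likelihood.** Each centered profile is Gaussian with a
   sample-specific covariance: x_i − x̄ ~ N_g(0, V_i). Log-transformed
   (microarray or RNA-seq) intensities are approximately Gaussian;
   untransformed counts are not, which is why the loader offers
   log2(v+1) and ln(v+1) transforms and the model expects log-scale
   input.
2. **Prior.** V_i ~ InvWishart((ν_i − g − 1) S_i, ν_i), where S_i is
   the sample covariance of the other N − 1 samples. The scale is chosen
   so the prior mean is exactly S_i: a priori, each individual's
   coexpression is centered on the population's.

Conjugacy gives the posterior V_i | x_1..x_N ~
InvWishart((ν_i − g) Σ_i, ν_i + 1) with mean

Σ_i = δ_i (x_i − x̄)(x_i − x̄)ᵀ + (1 − δ_i) S_i,  δ_i = 1/(ν_i − g).

Σ_i is a convex combination of a rank-1 PSD matrix and a PSD covariance,
so every estimated covariance — and the correlation matrix obtained by
r_jk = v_jk/√(v_jj v_kk) — is positive-semidefinite. This structural
guarantee is the method's main advantage over interpolation- or
z-score-based single-sample estimators, which are indefinite on
heterogeneous data.

The grand mean x̄ in the data term includes sample i (it is the
likelihood centering), while the prior mean S_i excludes it; both are
used exactly as the closed form dictates.

## Calibration of ν_i

The inverse-Wishart prior variance of a diagonal entry is
Var(v_i^(kk)) = 2 (s_i^(kk))² / (ν_i − g − 3). Summing over genes and
solving for ν_i:

ν_i = g + 3 + 2 Σ_k (s_i^(kk))² / Σ_k Var(v_i^(kk)).

Var(v_i^(kk)) is estimated empirically: leave out one sample at a time
to obtain N estimates η_1^k … η_N^k of gene k's variance, then take
their population variance (divisor N) η^(k). Substituting gives

δ_i = 1 / [3 + 2 Σ_k (s_i^(kk))² / Σ_k η^(k)] ∈ (0, 1/3],

with ν_i ≥ g + 3. The η^(k) are global (shared across samples) while
Σ_k (s_i^(kk))² is per-sample, exactly as the estimation procedure
defines them. Two consequences are tested as invariants: duplicating
the whole sample set shrinks every η^(k) and therefore every δ_i
(more homogeneous data ⇒ more weight on the population covariance), and
calibration is invariant to gene reordering.

Alternatively `delta` may be fixed to any value in (0, 1] for all
samples (ν = g + 1/δ); the calibrated route is the default.

**Degenerate cases.** If all η^(k) are zero (perfectly replicated
samples) the δ → 0 limit is returned, flagged, and Σ_i = S_i exactly.
Zero-variance genes are an error at load time (with an opt-in drop
flag) because they break both the calibration and the correlation
conversion.

## Covariance conventions

S_i is the *unbiased* covariance of the N − 1 remaining samples:
centered at their own leave-one-out mean, divisor N − 2. The same
convention is used for the leave-one-out gene variances η_j^k. A
maximum-likelihood divisor (N − 1) is available via
`cov_divisor="ml"`; the choice only matters at small N. All
leave-one-out quantities are obtained by downdating two global
accumulators (the sum vector and the sum of outer products), so one
pass over the data suffices and resident memory is O(g²) regardless of
N; tests verify the downdate against brute-force recomputation to
1e-10 relative.

## Edge significance and sparsification

The variance of an individual inverse-Wishart entry with scale
(ν − g − 1)S and df ν is

Var(v_jk) = [(ν − g + 1) s_jk² + (ν − g − 1) s_jj s_kk]
            / [(ν − g)(ν − g − 3)],

requiring ν − g > 3 (guaranteed by calibration). A Monte-Carlo test
validates the formula against 2×10⁵ inverse-Wishart draws. Because
inverse-Wishart quantiles have no closed form, the credible region for
v_jk uses a normal approximation: the null v_jk = 0 is rejected at
level α when 2(1 − Φ(|σ_jk|/ψ_jk)) ≤ α, where σ_jk is the posterior
mean entry and ψ_jk = √Var(v_jk). The absolute value makes the test
two-sided (the one-sided expression would exceed 1 for negative
estimates). Design choices here:

- By default the formula is evaluated at the prior-mean entries of S_i
  with the prior df ν (`edge_var="as-printed"`); algebraically this is
  the prior variance of the entry. `edge_var="posterior-params"`
  evaluates the identical formula at the posterior parameters (df
  ν + 1, mean Σ_i) for users who prefer a strictly posterior spread.
  Both are exposed because either reading is defensible; the default
  matches the published procedure.
- Diagonal p-values are computed and reported so the output stays a
  full g×g matrix, but they are untestable (a null of zero variance is
  meaningless) and should be ignored.
- Sparsification retains edges with p ≤ α (boundary included);
  Benjamini–Hochberg correction, when requested, is applied per network
  across its g(g−1)/2 distinct edges — each sample's network is a
  separate inference — via `statsmodels.stats.multitest`.

## Baselines

- **LIONESS::Pearson**: N·C_all − (N−1)·C_(−i) on Pearson correlation
  matrices; the interpolation formula comes from the LIONESS
  literature. Its entries overshoot [−1, 1] and its matrices acquire
  negative eigenvalues on mixtures — both reproduced as test
  properties, since they motivate the Bayesian estimator.
- **SPCC**: w_jk = z_ij z_ik with z-scores against the across-sample
  mean and population (divisor-N) standard deviation, so the average of
  w over samples is exactly Pearson r. The published description names
  only "a Z-test" for significance; here the null spread is the
  across-sample standard deviation of w_jk, a documented choice. The
  benchmark compares weights only, so this choice does not affect any
  comparative result.

SWEET is not implemented (its balancing weights are defined in its own
publication); externally computed dense networks in the package's TSV
format can be compared by hand.

## Synthetic-data generator

The generator emulates a cohort in which individual coexpression truly
varies, so that single-sample estimators have a well-defined target:

1. Population correlation: a Wishart-type draw (g × 2g standard-normal
   factor) normalised to unit diagonal — full rank with moderately
   strong off-diagonal structure.
2. Individual truth: V_i ~ InvWishart((ρ − g − 1)·Σ_pop, ρ) with
   `population_spread` ρ = g + 10 by default, so E[V_i] = Σ_pop and
   individuals scatter appreciably around the population (smaller ρ −
   g ⇒ more heterogeneity).
3. Ground truth for individual i: the empirical correlation of
   `truth_draws` = 500 held-out N(μ, V_i) replicates — the estimand is
   defined the same way for every method and carries the same
   finite-sample noise as a real replicate experiment. An analytic
   alternative (the correlation of V_i itself) backs the convergence
   test.
4. Observation: exactly one draw per individual, the regime
   single-sample methods face in practice.

Scenarios: `homogeneous` (one population); `mixture` (two populations
with independent covariances and means offset by `mean_offset` = 1.0
per gene; the minor share `mixture_fraction` defaults to 0.2 and the
minor-sample count is exact, e.g. 20 of 100); `gene_loss` (a fraction
`loss_gene_fraction` = 0.01 of genes is zeroed in
`loss_sample_fraction` = 0.2 of samples, in both observed and truth
draws, plus N(0, 1e-6²) jitter so variance-based machinery stays
defined — note the jitter is deliberate and loud). Exact distributional
parameters of the original benchmark are not public, so the benchmark's
acceptance properties are orderings and trends (who beats whom; how
error moves with N, heterogeneity, and sparsity), not absolute MSE
values.

Scoring: MSE = squared Frobenius norm between estimated and true
correlation matrices, averaged over samples; `scaled_mse` divides each
sample's MSE by the variance of its true correlation's upper-triangle
entries (the natural normaliser when comparing across g). For gene
loss, `lost_block_mse` restricts the error to off-diagonal edges
touching lost genes, over affected samples, which is where sparse and
dense estimates differ. Replicate seeds are spawned from the master
seed (`numpy.random.SeedSequence`), so replicates are independent but
the whole benchmark is reproducible bit-for-bit.

What passing the benchmark does **not** show: the generator draws
Gaussian data under the model's own likelihood family, so it validates
the estimator's statistical machinery, not robustness to count noise,
batch effects, or non-Gaussian expression in real data.

## Problem sizes and numerical choices

The shipped benchmark conditions are g = 100 with N ∈ {10, 50, 100} and
20 replicates per condition (the benchmark's qualitative orderings are
already stable there). Correlation entries may overshoot ±1 by at most
1e-12 before clipping — congruence preserves PSD exactly, so anything
larger is treated as a bug, not rounding. PSD assertions use the scaled
criterion λ_min ≥ −1e-8·λ_max. Estimation itself contains no
randomness: the CLI's `--seed` touches only simulation.

## Known limitations

- The prior centers every individual on the population covariance; for
  strongly multimodal cohorts the mixture scenario shows (and the
  benchmark quantifies) the resulting degradation.
- p-values rely on a CLT approximation to inverse-Wishart marginals;
  they are approximate at small ν − g.
- No FDR control across samples (only per network, optionally).
- No count normalisation, batch correction, or gene filtering beyond
  the zero-variance guard; inputs are assumed preprocessed.
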