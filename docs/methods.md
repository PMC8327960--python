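# Methods

## Model

For one trait, let `y_i` be the phenotype of animal `i` after
standardization (centering and scaling to unit sample variance; the `n-1`
convention, recorded in `StandardizationSpec` so back-transforms are exact)
and, when enabled, a monotone power transform (below). The model is

    y_i ~ N( mu + beta_sex * male_i + beta_mass * mass_i
             + u[sex_i, g_i] + c[center_i] + m[meta_i] + d[date_i], sigma^2 )

with `(u_f, u_m)_j` bivariate normal with zero mean, sex-specific SDs
`(sigma_f, sigma_m)` and correlation `rho` — the between-sex genetic
correlation of knockout effects (rfmK). Body mass is standardized the same
way. Environmental intercepts (phenotyping center, methodological
"meta-group", test date) are included only when their columns are present
and have at least two levels; dates are parsed as ISO-8601 calendar dates,
each distinct date one grouping level. Females are the reference sex;
`beta_sex` is the male offset.

Priors: N(0,1) on the intercept; N(0,2) on the mass effect; all group-level
and residual SDs half-Student-t(5, scale 1); `rho` uniform on [-1,1] (the
two-dimensional LKJ(eta=1) prior). The sex fixed effect has no stated prior
in the reference formulation (mixed-model software usually leaves
population-level effects flat); we give it N(0,2), the same family as the
mass effect, which is effectively flat at the standardized data scale.

The genotype effects are centered at zero, with the sex fixed effect
carrying the sex means. A formulation in which the bivariate effect
distribution itself has free means would be redundant with the intercept
and sex effect; zero-centered group effects resolve that redundancy the way
hierarchical-regression software does.

## Sampler

Sampling is by a blocked Metropolis-within-Gibbs scheme written directly in
numpy; the posterior contract is distributional, and the scheme is verified
by the recovery and calibration suite rather than trusted by construction.
Per sweep:

1. **Fixed effects** `(mu, beta_sex, beta_mass)`: exact multivariate-normal
   conditional (conjugate).
2. **G matrix** `(sigma_f, sigma_m, rho)`: adaptive random-walk Metropolis
   on `(log sigma_f, log sigma_m, atanh rho)` against the *collapsed*
   likelihood in which the genotype effects are integrated out — given the
   other terms, each genotype's cell means are bivariate normal with
   covariance `G + sigma^2 diag(1/n_f, 1/n_m)`. Collapsing removes the u–G
   coupling that otherwise makes `rho` mix slowly. Genotypes observed in one
   sex contribute their univariate marginal. Three substeps per sweep;
   Robbins-Monro step-size adaptation toward ~26% acceptance during warmup
   only.
3. **Genotype effects**: exact bivariate-normal conditionals given the new
   G, vectorized over genotypes (closed-form 2x2 precision and Cholesky).
4. **Translation sweeps**: the directions `(mu + d, u - d)`,
   `(beta_sex + d, u_m - d)` and `(mu + d, env_f - d)` leave the likelihood
   invariant, so `d` has an exact Gaussian conditional determined by the
   priors alone; sampling it eliminates the random-walk between intercepts
   and group-effect means that dominates autocorrelation in crossed designs.
5. **Environmental intercepts**: per factor, the scale is first updated by a
   1-D collapsed Metropolis step (level means marginal: variance
   `sigma_f^2 + sigma^2/n_k`), then the level effects by their exact normal
   conditionals.
6. **Residual SD**: half-t via the Huang-Wand inverse-gamma parameter
   expansion (two conjugate inverse-gamma draws).

Defaults are two chains of 8000 iterations with the first 4000 discarded,
matching the reference analysis; the desk-scale setting used throughout the
test suite is 2 x 2000 (1000 warmup), which gives minimum bulk ESS of a few
hundred and max split R-hat ~1.02 on generator-scale problems (J = 150
genotypes, 7 animals per sex) at roughly 2 s per fit. Divergence-based
criticism is specific to Hamiltonian samplers and is reported as
not-applicable (`divergent_frac = None`); the model-criticism gate skips
rules whose inputs are unavailable and otherwise fails a fit when max
R-hat > 1.05, divergent draws > 2.5%, or min bulk ESS < 400 (all
thresholds configurable). R-hat and bulk ESS use the rank-normalized split
definitions via arviz.

## Power transform

To make residuals approximately Gaussian the pipeline can estimate a
Box-Cox-type transform with a location/smoothing parameter:
`z = (y + sqrt(y^2 + gamma^2))/2`, then `(z^lambda - 1)/lambda`
(`log z` at `lambda = 0`). With `gamma > 0` the map is strictly increasing
on the whole real line. `(lambda, gamma)` maximize the profile likelihood of
Gaussian residuals from a fast two-stage approximation of the reduced model
`phenotype ~ mass + sex + (0 + sex | genotype)` — fixed effects by least
squares, genotype-by-sex effects as cell means shrunk by the standard
variance-ratio factor with moment-estimated components — including the
Jacobian of the transform. A full hierarchical fit per candidate pair would
be needlessly expensive; the estimator target (profile ML) is unchanged.

Search: lambda on a 0.1 grid over [-2, 2] refined by bounded scalar
optimization; gamma on a log grid capped at twice the data SD (far beyond
the data scale the intermediate map is affine and lambda loses
identifiability), followed by a joint Nelder-Mead polish of
`(lambda, log gamma)`; ties break toward `lambda = 1`. Lambda is not
rounded or bounded further. Recovery on generator output is typically
within ±0.1; occasional seeds reach ±0.25 for mid-range lambda because
lambda and gamma genuinely trade off at panel sample sizes.

Order of operations: standardize, then transform (the inverse pipeline
un-transforms, then un-standardizes). The estimator itself is agnostic to
the order and can be applied to raw data.

## Derived measures

- **rfmK**: posterior median and 50/80/95% central intervals of `rho`, plus
  the Fisher z-transform `atanh(rho)` (draws clamped to ±(1 - 1e-12)).
- **Variance ratio**: per draw `sigma^2` ratio, both folded
  (larger/smaller, >= 1 by construction) and male/female; log-scale
  summaries accompany both.
- **Riemannian distance**: G is scaled by the mean of its diagonal — the
  convention under which equal variances with `rho -> 1` reach the all-ones
  null — and compared with the ε-regularized null `[[1, 1-eps], [1-eps, 1]]`
  (`eps = 1e-3`, configurable; the exact null is singular) under the
  affine-invariant metric `||log(N^{-1/2} S N^{-1/2})||_F`, computed from
  the generalized eigenvalues of (S, N) in closed form. Distances are
  comparable across traits at fixed ε, which is all the downstream
  regression needs.
- **SD index**: per draw, female and male wild-type means are predicted at
  the average body mass (standardized 0; predicting at sex-specific mean
  mass is a config option), averaged across control backgrounds — each
  distinct wild-type background counts as its own control genotype — then
  mapped back to the original scale. The index is larger/smaller − 1 and
  requires a ratio-scale trait; the signed female/male ratio is always
  emitted. Draws whose back-transformed mean is non-positive are flagged;
  above 5% flagged the index is reported as not-computed.
- **ROPE classification**: dimorphic when the whole 95% CI of the SD index
  exceeds the ROPE upper bound (default 0.05), monomorphic when it lies
  entirely below it; otherwise unclassified.

## Meta-regression

Each architecture measure (Fisher-z rfmK, log variance ratio, log distance)
is regressed on the SD index with full uncertainty propagation: 500
datasets are resampled, each taking one *joint* posterior draw per trait
(preserving the within-trait correlation of measure and SD — sampling the
two independently is the alternative and discards that correlation); one
Gibbs chain of Bayesian simple regression runs per dataset (1000 kept
draws) and inference pools the concatenated chains. Second-stage priors —
unstated in the reference analysis, which used package defaults — are fixed
as slope N(0, 2.5·sd(y)/sd(x)), intercept N(mean(y), 2.5·sd(y)), residual
half-t(5, sd(y)). The intercept is the measure expected at monomorphism.

## Discordance ranking

Per trait and posterior draw, genotype effects rotate to
`concordant = |u_f + u_m|/sqrt(2)`, `discordant = |u_f - u_m|/sqrt(2)` and
become percentile ranks (average ranks at ties, scaled to (0, 100]).
Genotypes tested on at least `min_traits` traits (default 100; the
alternative documented threshold is 50) are averaged within draw across
traits and summarized over draws; 95% CIs come from 100 joint resamples
using the same draw fraction across traits, preserving cross-trait
posterior dependence within a genotype. Classification: more (less)
discordant than average when the CI lies entirely above (below) the 50th
percentile.

`approximate_effect_posterior` provides the exact conditional
genotype-effect posterior at *known* hyperparameters (cell-mean shrinkage);
it exists so the ranking stage can be validated on large truth-labelled
panels without hundreds of full fits, and absorbs environmental structure
into the residual — it is not a substitute for the full model on real data.

## Fertility association

Genes are sex-biased when |log2 fold change| >= 1 (2-fold on the linear
scale; the threshold's scale is configurable) AND the Benjamini-Hochberg
adjusted p-value clears alpha = 0.05; the log2 fold change is interpreted
as male minus female (configurable sign). The 3 x 4 bias-by-fertility table
is tested by Pearson's chi-squared (df = 6, no continuity correction —
Yates applies only to 2 x 2); expected cells below 1 raise a warning flag.

## Synthetic data

`simulate_trait` draws knockout effects from the configured bivariate
normal; wild-type (control) genotypes carry effects of exactly zero — they
define the population center, consistent with wild-types ranking low on
both rotated axes. Defaults mirror the panel design the pipeline targets:
7 animals per sex per genotype, 150 knockout genotypes plus 5 control
sub-strains of 50 animals per sex, 5 centers / 3 meta-groups / 30 dates
assigned uniformly at random, environmental SDs (0.2, 0.1, 0.1), residual
SD 0.5 against genetic SDs of 0.5 and rho 0.65, and sex-dimorphic body
mass (female 20 g, male 25 g, SD 2 g — generator conventions, not
empirical claims). An optional inverse power transform emits raw-scale
data for transform-recovery tests. `simulate_panel` shares one genotype
roster across traits and can plant genotypes with purely discordant
effects (`u_f = delta = -u_m`, default `delta = 3 sigma_f`) in every trait.
`simulate_fertility` draws a bias class per gene (defaults: 10% female-
biased, 10% male-biased, 80% unbiased) and a fertility outcome with
male-limited infertility at 11% for male-biased knockouts against a 1.5%
baseline; female-limited infertility (1%) and full infertility (0.5%) are
bias-independent generator conventions.

What the generator does *not* emulate: confounded environmental structure
(center-specific batches), trait-specific distributions of a real
phenotype catalogue, missing-data patterns, or sex-by-center interactions.
Passing recovery tests therefore demonstrates correctness of the inference
machinery under the stated model, not robustness to real-data pathologies.

## Problem sizes and numerical choices

The test and acceptance workloads run at desk scale by choice: 12-20
simulated traits of 150 genotypes for correlation recovery (posterior
median MAE ~0.05, 95% CI coverage ~95%), 60-genotype traits for ROPE
classification rates, 5 panels of 60 traits for discordance recovery, and
2 x 2000-iteration chains throughout. Degenerate inputs are defined
errors: constant traits, single-sex datasets, |rho| > 1, zero-margin
contingency tables, non-positive values under a gamma = 0 transform.
Ties in ranks use average ranks; ties in transform estimation prefer
lambda = 1; rho draws are clamped before atanh only at the 1e-12 level.

## Known limitations

- The Gibbs sampler's ESS at desk scale can fall below the 400 gate for
  variance components with few levels (e.g., a 3-level meta-group); the
  full 8000-iteration setting clears it.
- The ε-regularized distance depends on ε near the null; only its
  cross-trait comparisons at fixed ε are meaningful.
- The transform estimator's lambda is weakly identified when gamma is
  large relative to the data scale; the gamma cap is a pragmatic
  regularization.
- With very unbalanced sexes within genotypes the collapsed G update
  remains exact, but the approximate effect posterior used for ranking
  validation does not model environmental terms.
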