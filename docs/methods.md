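# Methods

## The observation model

The unit of analysis is one *observation*: a contrast between a genetically
diversified plant stand (≥ 2 genotypes) and its single-genotype control for
one response measure in one study.  Each observation carries two-group
summary statistics (means, SDs, group sizes), a trophic group (plant,
invertebrate herbivore, natural enemy of herbivores, weed, plant-feeding
nematode, plant disease), one of 16 concrete response categories mapped
deterministically onto those groups, and moderators (ecosystem, plant life
form, experiment type, climatic zone, number of added genotypes).  The
*plant antagonist* aggregate is the union of the herbivore, weed, nematode
and disease groups; it is always derived, never stored, so no observation is
double-counted.  Validation is strict and non-silent: rows violating an
invariant (negative SD, both SDs zero, pooled df < 3, inconsistent
category/group, unknown factor level) are returned in a rejects table with
reasons.

Indoor/greenhouse records carry `climate_zone = "indoor"` and are excluded
only from models that include the climatic-zone moderator.

## Effect sizes

For an observation with treatment/control means `M_t, M_c`, SDs
`sd_t, sd_c` and sizes `n_t, n_c`:

    s_p = sqrt(((n_t−1) sd_t² + (n_c−1) sd_c²) / m),   m = n_t + n_c − 2
    d   = (M_t − M_c) / s_p
    J   = 1 − 3/(4m − 1)
    g   = J d
    v   = (n_t+n_c)/(n_t n_c) + (1 − (m−2)/(m J²)) g²

`v` is Hedges' (1983) unbiased sampling-variance estimator (the "UB" type
of the standard meta-analysis packages); the test suite audits `g` and `v`
against metafor's `escalc(measure="SMD", vtype="UB")`, which uses the exact
gamma-ratio correction instead of the `1 − 3/(4m−1)` approximation —
agreement is to about 1e−4.  Signs are kept as reported; no directional
recoding is applied anywhere.  Observations with both SDs zero are rejected
rather than imputed.

## Multilevel meta-regression

The marginal model for the effect-size vector `y` with known sampling
variances `v_i` is

    y ~ N(Xβ, V),
    V = diag(v_i) + τ²_sp,phylo · Z_sp R Z_spᵀ + τ²_sp,iid · Z_sp Z_spᵀ
        + τ²_study · Z_st Z_stᵀ + τ²_obs · I

with species (`Z_sp`) and study (`Z_st`) incidence matrices.  `R` is the
Brownian-motion correlation among species — covariance proportional to
shared branch length from the root, rescaled to unit diagonal; the
construction is valid for non-ultrametric trees.  The species effect can be
split into a phylogenetically correlated and an iid part, or either part
fixed at zero; species absent from the supplied tree receive the iid
component only (with a warning).  The observation-level component implements
effect sizes nested within studies.

Variance components are estimated by REML on the scale `log(τ² + ε)`,
`ε = 1e−10`, with L-BFGS-B (`ftol 1e−13`), one dispersed restart by default
(`n_restarts` configurable; restart draws come from a config seed, default
20221127), ties broken by highest restricted likelihood then smallest total
heterogeneity.  Fixed effects are the GLS solution at the optimum.  Rows
are internally sorted into a canonical order so every reported number is
exactly invariant to the input permutation.  An audit helper verifies each
fit against 64 random perturbations of the variance components; with all
τ² = 0 the estimator reduces to the closed-form inverse-variance-weighted
mean (tested to 1e−10), and the whole fit is cross-checked against metafor's
`rma.mv` (note metafor's restricted likelihood adds a `+½ log|X'X|`
constant).

Inference on category means uses t statistics with `df = n_obs − p`,
matching the reported-output convention of the software family this design
follows.  Likelihood-ratio tests for fixed-effect terms refit both models by
ML (REML likelihoods are not comparable across fixed-effect structures, and
the code refuses to compare them); variance-component tests may use REML.
Designs are built with cell-means coding for the first categorical term and
treatment coding for subsequent ones; empty levels are dropped with a
warning, rank deficiency is an error naming the aliased columns.

## Genotype-number trends

Effect sizes are regressed on `x = log₂(number of added genotypes)` by GLS
with the exponential variance function `Var(ε_i) = σ² exp(2δ μ̂_i)`, the
variance covariate being the fitted values (the default of the `varExp`
construction this mirrors).  For fixed δ the coefficients solve a damped
fixed-point of weighted least squares; δ is then profiled by bounded scalar
optimization (convergence `|Δll| < 1e−8`).  δ = 0 reduces exactly to OLS.
Slope inference uses t with `df = n − 2`; σ² for standard errors is the
REML-type `RSS_w/(n − p)`.  Pointwise 95% bands come from the coefficient
covariance; grid points outside the observed range are flagged, not
refused.  Error *correlation* (beyond heteroscedasticity) is not modelled
in v1.  Trend models are unweighted by `v_i`, matching the plain GLS call
they reproduce; this is noted as a sensitivity-analysis hook.

## Piecewise SEM

A SEM is a DAG over an exogenous diversity measure and the SMDs of trophic
groups, with one component model per endogenous node.  The component model
is the same marginal machinery as the meta-regression: response SMD with
fixed weights `1/v_i` (the residual scale is fixed at 1, so the residual
variance equals the sampling variance), a between-study random intercept,
and a free observation-level heterogeneity component.  The last term is a
deliberate design choice: with the residual pinned exactly at `v_i`, any
true effect variation beyond sampling error makes the d-separation tests
anticonservative; the extra component absorbs it and restores calibration
(verified by simulation).  Grouping factors absent from a subset (site,
plot) are dropped for that subset.

The d-separation basis contains one claim per non-adjacent pair,
conditioned on the union of both nodes' parents (the standard basis; for
the DAGs in scope this coincides with conditioning on the later node's
parents alone).  Each claim is tested by adding the earlier variable to the
later variable's component model and reading its Wald-t p-value; Fisher's
`C = −2 Σ ln p_i` is referred to χ² with `2k` df.  A saturated DAG has an
empty basis: `df = 0` and no global test is emitted.  Zero p-values are
clipped to 1e−16 with a warning.  Indirect effects are reported as products
of path coefficients, without standard errors.

The exogenous diversity node defaults to `log₂(added genotypes)`, which
varies across contrasts and thus identifies the diversity paths; a binary
diversity indicator is only identifiable if the data contain zero-diversity
contrasts, and is supported for that case.  Pairs and triples are joined on
the finest key available in all subsets — (study, site, genotype-number
contrast) — and multiple same-group observations within a cell are combined
by inverse-variance weighting before pairing.

## Publication bias

The regression test appends each observation's sampling variance `v_i`
(optionally its square root) as a moderator to an established mixed model
and reports that coefficient's t and p; a variance column collinear with
the design is an error.  The fail-safe number uses signed per-observation
z-scores `g_i/√v_i` as reported:
`N = max(0, ⌈(Σz)²/z_α² − k⌉)` at one-tailed α = 0.05.  In a corpus with
opposite-signed strata the full-corpus Stouffer sum partially cancels, so
direction-consistent strata are the more informative summaries.
Trim-and-fill is deliberately absent: it is defined only for models without
moderators.

## The synthetic generator

Each observation's true standardized difference is

    θ = μ_group + b·log₂G + u_species + u_study + u_obs,
    u_species ~ MVN(0, τ²_sp [λR + (1−λ)I]),  u_study ~ N(0, τ²_study),
    u_obs ~ N(0, τ²_obs),

after which two normal arms with standardized difference θ are actually
sampled and summarized, so the effect-size formulas face realistic noise
(a fast mode draws `d` from its sampling distribution directly for large
calibration runs).  `R` comes from a simulated pure-birth tree (`sp_1…sp_n`;
the correlation structure of such a tree is invariant to the birth rate,
which only rescales depth).  One random stream is forked per study, so
extending the corpus never perturbs existing studies.  Defaults: 150
studies of 2–6 observations; group shares 40% plant / 25% herbivore / 15%
disease / 10% enemy / 6% weed / 4% nematode; planted means plant +0.35,
enemies +0.75, herbivores −0.60, weeds −0.10, diseases −1.10, nematodes
−2.00 (echoing the magnitudes such corpora report); τ²_study = 0.10,
τ²_obs = 0.05, τ²_sp = 0.05, λ = 0.5; arm sizes 5–30; genotype levels
{2, 3, 4, 6, 8}; seed 20221127.  Tri-trophic links are generated from the
linear DAG `θ_E = a_DE x + …`, `θ_H = a_DH x + a_EH θ_E + …`,
`θ_P = a_DP x + a_HP θ_H + …` with study intercepts and unit exogenous
noise, and a bookkeeping table of planted contrasts.  Optional censoring
drops results nonsignificant in a chosen direction with a given
probability, emulating publication bias.

What the generator does *not* emulate: the real corpus's exact moderator
frequencies and within-study designs, figure-digitisation error, correlated
responses measured on the same plots, or selective reporting subtler than
the threshold-censoring rule.  Passing tests therefore demonstrate
correctness of the machinery under the stated model, not robustness to
every feature of real literature data.

## Simulation scales and numerical choices

Test simulations are scaled to single-CPU desk runs: CI coverage uses 500
replicates of 80 balanced studies with moderate planted means (|μ| ≤ 0.75);
LRT null calibration uses 500 replicates of 100 studies × 4 observations
(with 50 studies the χ²₁ reference for the ML LRT is visibly
anticonservative); d-separation and bias-test calibrations use 500
replicates each; path recovery and end-to-end mean recovery use 200
replicates at the default 150-study scale.  Recovery and calibration fits
use the moment start without restarts — the 2–3-parameter REML surfaces
there are smooth, and local optimality is audited separately.

## Known limitations

- Inverse-variance weighting of SMDs is mildly attenuating because `v`
  grows with `g²`: precise-looking small effects are upweighted.  At the
  default arm sizes the bias is negligible for |θ| ≤ 0.8 (< 0.04) but
  reaches ≈ +0.10 for the nematode-scale |θ| = 2, and CI coverage degrades
  accordingly in that regime.  This is a property of the estimator family,
  shared with the standard software, not of this implementation.
- For the same reason the variance-as-moderator bias test is only
  calibrated in the moderate-effect regime: at |θ| ≈ 2 the `g²` term
  mechanically couples each effect to its own variance, and the regression
  test rejects ≈ 10% of null (uncensored) corpora.  Its p-values for
  strata with extreme standardized effects should be read with that caveat.
- t inference uses `df = n_obs − p` throughout; no Knapp–Hartung or
  cluster-robust adjustment (out of scope for v1), so per-category CIs can
  be slightly narrow when a category's observations concentrate in few
  studies.
- The GLS trend stage models heteroscedasticity only; no spatial/temporal
  correlation structures.
- SEM indirect effects carry no standard errors; latent variables and
  covariance-based SEM are out of scope.
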