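# Methods

## Effect sizes and screening

The unit of analysis is one control/treatment comparison.  The effect size
is the delta log response ratio: the naive `ln(m̄_T/m̄_C)` is biased by
`(r_C − r_T)/2` with `r = s²/(n m̄²)` (second-order Taylor), so the estimator
adds `(r_T − r_C)/2`, and its sampling variance is the matching second-order
expression `r_T + r_C + (r_T² + r_C²)/2`.  A first-order (two-term) variance
is available via `variance_order="first"`.  Simulation confirms the
corrected estimator is centred on the true log ratio to 3 decimal places at
10⁶ replicates across group sizes 3–20 and CVs up to 0.5.

Groups with means too close to zero break the log-normal approximation; the
Geary statistic `(m̄/s)·√n` with the classical threshold 3 screens them.  A
record is dropped only when *both* groups fail (a stricter either-fails rule
sits behind a flag).  A zero SD yields an infinite statistic (pass) and
contributes nothing to the bias correction or variance; all-or-nothing
germination outcomes produce such records, and a variance floor of 1e−12
keeps downstream weights finite when both SDs vanish.

## Dose imputation

Dose enters the model as a categorical random effect, so missing doses
(≈23% of the compiled comparisons) are imputed first.  With one incomplete
variable the chained-equation cycle reduces to a single conditional model;
we run m = 25 predictive-mean-matching imputations — Bayesian linear
regression of log10(dose) on the effect size, its SE and the remaining
moderators, type-1 matching with 5 donors — within each dose-unit class
(doses span orders of magnitude; PMM never leaves the observed range), and
take the per-record median.  Observed doses are never modified, everything
is deterministic under the seed, and an audit table retains all draws.
Categories are doses rounded to 2 significant figures, prefixed by unit
class; both the rounding rule and the log-scale treatment are package
decisions exposed in the API (the upstream convention states only that dose
was rounded and categorized).

## Phylogeny

A user-supplied rooted Newick tree with branch lengths covers every grass
and recipient species.  Patristic distance PD is the path length between
tips; the distance covariate is log(1 + PD) so conspecific pairs (PD = 0)
are defined.  The correlation matrix for tree-linked random effects is
`A(x, y) = shared branch length / √(depth_x · depth_y)`, which has unit
diagonal on any tree and reduces to shared-depth-over-height on ultrametric
trees; non-ultrametric trees are accepted with a warning.  A 1e−8 diagonal
jitter is added before factorization.

## The hierarchical model

```
y_i ~ Student-t(ν, μ_i, √(σ² + se_i²))
μ_i = [b0_study + u_study + u_substudy + u_trait + u_method + u_duration + u_dose]
    + [b0_species + β_g·NN(grass) + β_r·NN(recipient) + f(logPD)
       + u_grass + u_recipient + w_grass + w_recipient]
```

* Known sampling error and residual heterogeneity combine on one scale
  `√(σ² + se_i²)` under a single Student-t with one shared ν (> 1); heavy
  tails absorb outlying effect sizes.
* Nested factors are coded as combination levels (study/substudy,
  study/substudy/trait, method/duration).  Tree-linked effects `w` are
  MVN(0, τ²A) over the full species panel, shared between grasses and
  recipients.  Single-level factors are dropped with a warning.
* `f` is a low-rank penalized spline of log-distance: a cubic B-spline basis
  with quantile knots and a second-difference penalty, eigen-reparameterized
  so the penalty range becomes exchangeable "wiggly" columns with one
  smoothing SD (another τ) and the null space contributes a single linear
  column — the reportable distance coefficient.  Wiggly columns are
  orthogonalized against [1, x] and centred; with < 4 distinct covariate
  values the term degrades to linear-only (logged).
* Priors: intercepts and fixed effects N(0, 1); every τ and σ
  half-Student-t(3, 0, 2.5); ν ~ Gamma(2, 0.1) truncated at 1.  All
  overridable via `Priors`.
* The intercept-only model omits the fixed effects and the smooth but keeps
  every random effect.

**Identifiability caveat.**  μ is a sum of two components with separate
intercepts, so only `b0_study + b0_species` is data-identified; the addends
are split only by their priors.  Every summary reports `b0_sum` alongside
the addends, and downstream quantities (cell predictions, residuals) use
the sum.

## Sampling

Fitting is by a blocked Gibbs sampler.  The Student-t is represented as a
normal scale mixture with per-observation Gamma(ν/2, ν/2) weights, making
every location block conditionally normal: one joint multivariate-normal
draw for all scalar coefficients (both intercepts, origin effects, smooth
linear terms), a small solve for each wiggly block, independent per-level
draws for iid factors, and a q×q Cholesky solve for tree-linked factors.
Variance components use half-t priors through the inverse-gamma parameter
expansion (conjugate updates).  Three mixing devices matter in practice and
are part of the design:

1. **Recentering sweeps** — a shift of a side's intercept (or of an origin
   coefficient) is likelihood-invariant when compensated by the aligned
   subset of factor effects; that direction is resampled exactly from the
   priors after each factor update.
2. **Interweaving (non-centred) τ moves** — a log-scale Metropolis step that
   rescales τ with the standardized effects held fixed, which traverses the
   funnel at small τ.
3. **Collapsed σ/ν updates** — adaptive log-scale Metropolis against the
   marginal Student-t likelihood (weights integrated out), after which the
   weights are redrawn; this decouples (σ, ν) from the latent scales.

Defaults: 4 chains × 2000 iterations (1000 warmup), seeded; R-hat and ESS
per scalar parameter via `arviz`, with a warning above R-hat 1.05.
Per-observation μ draws are stored, so pointwise Student-t log-likelihoods,
PSIS-LOO, WAIC and meta-analytic residuals are exact functions of the draws.

## Inference

Hypothesis contrasts are single coefficients (NWH: grass origin; BRH:
recipient origin; PDH: the smooth's linear coefficient), all predicted
negative a priori.  Intervals are equal-tailed posterior quantiles;
`p_direction` is the posterior mass on the predicted sign; `supported`
requires the predicted side's bound to exclude zero at the chosen level.
Cell predictions combine `b0_sum`, the origin coefficients and the smooth
evaluated at the cell's mean log-distance.  Variance decomposition (defined
on the intercept model) reports the posterior mean of
`τ_r² / (Σ τ² + σ²)` per draw; the ratio-of-posterior-means variant is
computed alongside, and a flag inflates σ² by ν/(ν−2).  Model comparison
uses PSIS-LOO and WAIC with a warning when > 10% of Pareto-k values exceed
0.7.

## Bias diagnostics and power

Egger's regression runs on the intercept model's meta-analytic residuals
(observed minus posterior-mean fitted value, random effects included):
`e_i = a + b·se_i` with weights `1/se_i²`, the intercept `a` as the bias
statistic with a frequentist t-based CI (the SND variant sits behind a
flag).  The funnel export adds zero-centred 90/95/99% contour bounds that
collapse at se = 0.  The year-trend check refits the intercept model with a
smooth of `log(year − min_year + 1)` in the study component and reports the
linear coefficient's CI.

Power uses the standard random-effects formulation: per-study variance
`v = (n1+n2)/(n1·n2) + d²/(2(n1+n2))`, between-study variance `τ² = h·v`,
noncentrality `λ = d/√((v+τ²)/k)`, and two-tailed normal power.  The
heterogeneity mapping keeps the classical low/moderate ratios h = 0.33 and
0.67; the "high" ratio is **calibrated to h = 1.05** so that the reference
design (k = 23, n = 20/20, d = 0.288) returns 86% at integer rounding,
matching the convention of the calculator the reference analysis used
(h = 1.0 gives 86.7% → 87).  The calibration lives in
`HETEROGENEITY_RATIOS`, is overridable per `PowerSpec`, and is deliberately
documented rather than hidden.

## Synthetic data

The generator mirrors the compiled-literature structure: 23 studies with
1–3 sub-studies, 1–2 traits, 1–5 recipients and 1–4 doses each (~520
effects at the defaults), species assigned at random across a unit-height
pure-birth tree so grass–recipient pairs span divergence depths, origins
drawn at 50% non-native, doses log-normal within method-specific unit
classes, 23% of doses blanked completely at random, and two deliberate
low-signal records that fail the Geary screen in both groups.  Latent
effects follow exactly the model's two-component structure; default taus
size each factor's share of a total variance of 0.25 (residual share 0.07),
ν = 5, and the default coefficients are the compiled analysis' headline
values (intercept sum −0.26, grass origin −0.14, recipient origin +0.09,
distance slope −0.22).  Raw group statistics are then realized so that the
delta-LRR of a record is a noisy unbiased estimate of its latent effect:
log-normal control means, treatment mean `m_C·e^y`, group sizes 4–20, CVs
0.05–0.35, sample SDs with chi-square noise.

What the generator does **not** emulate: publication bias and correlated or
informative missingness (available only as explicit options in tests),
realistic taxon names, and between-study differences in dispersion
reporting.  Passing recovery tests therefore show the pipeline is correct
and calibrated *under the stated generative assumptions*, not that any
particular real compilation satisfies them.

## Problem sizes used by the test and acceptance suites

Coverage is assessed on 20 replicates of 500 effects (2 chains, 1000
iterations, 500 warmup per fit) and bias on 10 replicates of 2000 effects
with a wider species panel (30 grasses, 50 recipients), sizes chosen to
make the Monte-Carlo error of the bias estimate (~0.02) small against the
0.05 criterion.  The model-comparison check uses 20 seeds of 350 effects
with deliberately strong origin effects (−0.5/+0.4) and small species-level
taus so that the fixed effects, not the exchangeable species effects, carry
the signal the full model can exploit.  The Monte-Carlo effect-size oracle
uses 10⁶ replicates per parameter set.

## Known limitations

* The two-intercept split is prior-identified only (reported prominently).
* Origin contrasts are species-level comparisons: with ~14 grass species
  their posteriors are wide and dominated by between-species variance, so
  single-dataset point estimates scatter around truth even at large n.
* Gibbs mixing for weakly identified taus (few levels, small truth) is the
  slowest in the sampler despite interweaving; the R-hat surface flags it.
* The Egger CI is frequentist, and the power calculator's "high" mapping is
  a documented calibration, not a derivation.
* Replication of the compiled analysis requires the third-party data files
  and is scale-faithful only with the original distance matrix, since an
  arbitrary user tree fixes the smooth only up to the covariate's scale.
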