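# Methods

## Model

Each study is a two-arm design: treatment indicator T (control = 0),
mediator M (a neurogenesis assay: cells or cells/mm³), behavioural
outcome Y. Within a study both M and Y are standardised to mean 0 and
sample SD 1 (n−1 denominator), **pooled across the two groups** — per-group
standardisation would remove the very group contrast the model estimates.
Standardisation only puts studies on a common SD scale; it does not
otherwise change them. Outcomes bounded in (0, 100) percent are mapped to
the logit scale, log(p/(1−p)) with p = value/100, before standardisation
so that a normal linear model applies.

The mediation model is the pair of linear regressions

    M = α_M + β1·T + ε_M,     ε_M ~ N(0, σ_M²)
    Y = α_Y + β3·M + β4·T + ε_Y,   ε_Y ~ N(0, σ_Y²)

The indirect (mediated) effect is β1·β3, the direct effect β4 and the
total effect their sum; all are reported in outcome-SD units. The product
β1·β3 is summarised from joint posterior draws, so its skewed small-sample
distribution is handled exactly rather than by a delta-method normal
approximation. Key assumptions: linear, additive effects (no strong
group × mediator interaction — the association module warns when the
interaction t-test has p < 0.05); behavioural testing does not itself
alter the mediator differentially between groups; the mediator varies
within groups; and no unmeasured variable drives both M and Y. The
analysis is a necessary, not sufficient, condition for mediation.

## Sampling

Under a flat prior on coefficients and p(σ²) ∝ 1/σ² each regression has a
normal–inverse-gamma posterior, so the default sampler draws *independent
exact* posterior samples: σ² from SSR/χ²(n−p), then coefficients from
N(β̂, σ²(XᵀX)⁻¹). Posterior means therefore coincide with the
least-squares estimates up to Monte-Carlo error, which the test suite
uses as an oracle. Defaults are 3 chains × 20,000 retained draws; burn-in
and thinning are no-ops for independent draws but are honoured by the
alternative Gibbs sampler (method="gibbs"), which alternates β | σ² and
σ² | β and also supports the weakly informative prior
(coefficients N(0, 100²), error variances inverse-gamma(0.001, 0.001)).
Long Gibbs protocols (e.g. 10⁶ iterations, burn-in 5000, thin 10) can be
requested through the same config. Convergence is checked with the
Gelman–Rubin potential scale reduction factor
R̂ = sqrt(((n−1)/n·W + B/n)/W); any parameter above 1.01 flags the fit
with a warning instead of aborting a multi-study run.

Effects are reported so that positive means better performance: for
declared lower-is-better outcomes the outcome-equation draws (α_Y, β3,
β4) are negated after fitting, which flips indirect, direct and total
consistently and is an involution. Negating estimates rather than data
keeps the per-study fit interpretable on the study's own scale.

## Pooling

A study's effect enters the meta-analysis as the posterior mean y with
posterior variance v. When a study contributes several outcomes or
mediator markers, only the most precise estimate (smallest v) is pooled,
avoiding double counting of animals; ties break deterministically by
declared primary-outcome order, then lexical label, and the selection is
recorded in the report. The between-study variance τ² solves the
empirical-Bayes / Paule–Mandel estimating equation
Σ wᵢ(τ²)(yᵢ − μ̂(τ²))² = k−1 with wᵢ = 1/(vᵢ+τ²), iterated by damped
Newton steps from a DerSimonian–Laird start to |Δτ²| < 1e-8 (max 100
iterations, convergence error reporting the last iterate otherwise) and
truncated at 0. Its standard error uses the large-sample form
sqrt(2k²/(k−1))/Σwᵢ, the same expression metafor reports for this
estimator, against which the implementation is cross-checked on frozen
fixtures. Heterogeneity is tested with Cochran's Q (fixed-effect
inverse-variance weights) against χ² with k−1 df. Pooled inference is
normal-theory: CI = μ̂ ± z₀.₉₇₅·se, p = 2·Φ(−|μ̂/se|); no Knapp–Hartung
adjustment. The mediated and other-mechanism effects are pooled in two
independent meta-analyses, and the headline "percent of the total effect
through the mediator" is 100·indirect/(indirect+direct) of the pooled
means, with a suppression warning when the two components disagree in
sign.

## Association diagnostic

The individual-level test of "more neurogenesis → better behaviour" is
the mediator slope in the ANCOVA Y ~ T + M (common slope, residual df
n−3), reported next to the naive pooled regression Y ~ M. A pooled slope
that is significant while the within-group slope is not flags the
ecological-fallacy pattern: an aggregate association manufactured by
group offsets.

## Synthetic data

The generator draws studies from the same graph the model estimates:
M = b1·T + N(0, σ_m), Y = b3·M + b4·T + N(0, σ_y), on a raw scale so the
pipeline's own standardisation is exercised; percent-bounded outcomes go
through the inverse logit onto (0, 100). Raw coefficients map to
population standardised effects in closed form (via the population SD of
Y), and `spec_for_effects` inverts the map. The defaults emulate the
conditions of the small-animal literature the pipeline targets: 10
animals per arm (k = 11 studies ≈ 220 animals), b1 = 1.5 (a strong
mediator response to treatment), unit residual SDs, and (b3, b4) solved
so the population standardised indirect effect is 0.15 and the direct
effect 1.06, with zero between-study heterogeneity. Ensembles derive
child seeds deterministically as SeedSequence([ensemble seed, study
index]); with τ²between > 0 each study's coefficients are re-solved so
its true standardised indirect effect is the base value plus a
N(0, τ²between) deviation.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: figure-digitisation error, litter effects
and other clustering, selective reporting and publication bias,
non-normal or heteroscedastic outcomes, unmeasured confounding of the
mediator–outcome path, and group × mediator interactions. Simulation
results validate the machinery under its own assumptions, not the
literature.

## Numerical and design choices

- Exact conjugate sampling is the default because the model is two linear
  regressions; a generic MCMC adds autocorrelation without changing the
  posterior, and sensitivity to the (non-informative) prior is negligible
  on standardised data — the weak-normal Gibbs path exists to check this.
- Studies with more than two groups are rejected with a clear error; the
  model has a single treatment path and pooling takes one estimate per
  study. Multi-arm designs should be split into control-vs-arm contrasts
  upstream if that is scientifically defensible.
- Logit boundary values (exactly 0% or 100%) are rejected by default; an
  explicit opt-in clamps p to [ε, 1−ε] (ε default 0.005), because silent
  clamping can bias estimates.
- Sampler and pipeline randomness derive from `numpy` SeedSequence
  spawning; per-study fit seeds come from (pipeline seed, study index),
  so runs are bit-reproducible and adding a study does not perturb the
  draws of earlier ones.
- Degenerate designs (mediator constant within groups, zero residual
  variance, near-singular Gram matrix, condition number > 1e12) raise
  typed errors; in pipeline runs such studies are recorded as skipped
  with the reason and the run continues.
- Statistical tolerances in the test suite: simulation-based checks
  (coverage, calibration, recovery) use seeded replicates with bounds set
  from the binomial/Monte-Carlo error of the replicate count; exact
  identities (elementwise product, total = direct + indirect,
  orientation involution) are asserted exactly.

## Problem sizes

Default validation sizes were chosen to keep the whole suite fast while
leaving Monte-Carlo error well inside the asserted bounds: 50 studies for
the least-squares oracle comparison, 500 studies (n = 20/arm) for
coverage/bias calibration, 2000 ensembles (k = 12) for the Q-test type-I
rate, 50 random ensembles for the τ² grid-search cross-check, and 11–12
study ensembles of 10/arm for end-to-end runs.

## Known limitations

- Only two-group designs; no multi-arm or factorial (2×2) support.
- One mediator; multiple-mediator or confounder-adjusted models are out
  of scope.
- Study-level effects enter pooling as (mean, variance) summaries; the
  meta-analysis is frequentist, not a joint hierarchical Bayesian model.
- The percent-mediated summary is unstable when the total effect is near
  zero and can leave [0, 100] under suppression; it is reported with a
  warning in that case.
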