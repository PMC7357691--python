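# Methods

This note records the statistical models behind `trialkit`, the defaults and
numerical choices, and what the synthetic-data generator does and does not
emulate.

## Type-I-error inflation under an unplanned sample-size increase

A two-arm trial tests with a two-sided log-rank statistic at its planned
size N₁; finding no significance, it enrolls to N₂ and tests again at the
same unadjusted critical value c = z₁₋α/₂. Under the null the two
statistics (Z₁, Z₂) are asymptotically standard bivariate normal with
correlation ρ = √(D₁/D₂), where D_k = d·N_k is the expected number of
events and d the event proportion — the standard joint law of sequential
log-rank statistics, in which the information ratio drives the correlation.
The overall error

    α_overall = 1 − P(|Z₁| ≤ c, |Z₂| ≤ c)

is computed by conditioning on Z₁ and integrating the resulting
one-dimensional normal expression with adaptive quadrature (absolute
tolerance 1e−12, far below the 1e−6 contract). Bounds: α at ρ = 1 and
1 − (1 − α)² at ρ = 0; α_overall is nonincreasing in ρ. The second look
deliberately reuses the naive unadjusted critical value — the procedure
being criticized — not an alpha-spending boundary; no spending designs are
provided.

For the lopinavir-ritonavir design (N₁=160, N₂=199, d=0.75, α=0.05) this
gives α_overall ≈ 0.0707, reported as 0.071.

## Mixture terminal (cure) rate model

Event time T = (1 − η)T* + η·∞, with η ~ Bernoulli(γ_arm) the latent
terminal label (subjects who can never reach the good end point — e.g.
deaths when the end point is clinical improvement) and T* a proper latency
time. The population cumulative incidence is F_T(t) = (1 − γ)F_T*(t),
plateauing at 1 − γ < 1.

Fitting is EM:

* **E-step** — censored subject i gets susceptibility weight
  w_i = (1 − γ)S*(t_i) / (γ + (1 − γ)S*(t_i)); events have w = 1.
* **M-step, incidence** — the incidence model has arm as its only
  covariate, so the logistic MLE is saturated and solved in closed form:
  γ̂_arm is the arm's mean terminal weight (1 − w).
* **M-step, latency** — case-weighted proportional-hazards fit with the
  arm indicator: Cox partial likelihood with Breslow ties and Breslow
  baseline (default), or Weibull MLE (`latency="weibull"`). For a single
  binary covariate the partial likelihood reduces to a scalar Newton
  iteration over suffix sums of the two groups' risk weights; this package
  implements that special case directly (validated against a
  general-purpose Cox implementation in the tests) because the EM refits it
  every iteration and the bootstrap thousands of times.

Since the Breslow estimator is the profile maximizer of the weighted full
likelihood given β, the M-step maximizes the complete-data likelihood
jointly over (β, Λ₀), so the observed-data log-likelihood — recorded every
iteration in `loglik_trace` — is nondecreasing; the tests assert this with
a 1e−7 relative slack for floating-point noise. Convergence: maximum
change in (γ̂₀, γ̂₁, weights) below 1e−6, cap 500 iterations;
non-convergence is flagged on the result, never silent.

The semiparametric fit uses the usual zero-tail constraint: S*(t) = 0
beyond the last event time, so subjects censored after the last event
carry posterior terminal weight 1. Consequence: under administrative
censoring at the horizon τ, γ is identified only when essentially all
susceptible subjects have their event by τ ("sufficient follow-up");
otherwise latency mass beyond τ is absorbed into γ̂. This is a documented
assumption, not something the fit verifies.

Uncertainty: nonparametric bootstrap, resampling subjects within arm
(default 1000 replicates). CIs are percentile; P values use a normal
approximation z = estimate / bootstrap-SE (the difference in terminal
fractions is reported in percentage points, the latency effect as a hazard
ratio). Replicates that lose all events in an arm are dropped and counted.

## Restricted mean time-to-event

RMST(τ) = E[min(T, τ)] = area under the Kaplan-Meier curve on [0, τ]. For
improvement/recovery end points the identical number is the restricted
mean time to improvement/recovery (RMTI/RMTR), the area above the
cumulative incidence curve; the identity RMST + area-under-incidence = τ
holds exactly and is asserted to 1e−9. Variance is the standard
restricted-mean form Σ_j A_j² d_j/(n_j(n_j − d_j)) with A_j the remaining
area from t_j to τ (terms with A_j = 0 are dropped, which also covers an
exhausted risk set). Between-arm differences use an unpooled z contrast,
reported treatment-minus-reference; reference arms named control /
standard care / placebo are recognized automatically. τ beyond the
observed follow-up raises an explicit extrapolation error unless the
survival curve has already reached zero (then the area is fully
determined).

Percentiles: the time at which the cumulative incidence first reaches p,
with bootstrap percentile CIs (within-arm resampling) and a
normal-approximation P for the difference. Levels the incidence never
attains (e.g. above a cure-fraction plateau) are flagged undefined rather
than propagated as NaN.

## Pseudo-IPD reconstruction

A digitized cumulative-incidence curve (ordered time/incidence
coordinates) plus the arm size is converted to subject records: events per
step are the arm size times the incidence increments, apportioned by
largest-remainder rounding (ties to earlier times) so the total equals
round(arm_size × final incidence); everyone else is censored at the
horizon, consistent with the source trials' day-28/30 administrative
censoring. No at-risk table is consumed — the source figures carry none —
so interval-censoring refinements of the Guyot type are out of scope. A KM
refit of the output reproduces the input curve at every coordinate within
1/arm_size, and subject counts are conserved exactly.

## Bootstrap sample-size projection

With N₀ subjects enrolled of a planned N, each bootstrap replicate builds
a completed trial stratified by arm (so a published target allocation such
as 302:151 is met exactly): *unconditional* replicates redraw all N with
replacement; *conditional* replicates keep the observed subjects and draw
only the shortfall. Each replicate is refit with the two-arm Cox model
(Breslow ties). The predicted log-HR is the mean replicate log-HR; the
interval is Wald with the mean replicate model SE — chosen because it
makes the predicted interval width shrink as the target grows, the
qualitative behavior sample-size projection exists to show; a
percentile-of-replicates interval is available (`ci_method="percentile"`).
Conditional projection at the observed size involves no resampling and
returns the plain Cox fit exactly. Default 50 000 replicates; the test
suite uses 2000. Failed replicates are dropped, counted, and flag the
result above 10%.

## Contingency analyses

2 × c outcome tables use Pearson chi-square without continuity correction,
switching to a Fisher exact test when any cell is below 5. The Fisher test
fully enumerates tables with the observed margins under the multivariate
hypergeometric null and sums probabilities not exceeding the observed
table's (point-probability two-sided rule, with the customary 1 + 1e−7
tolerance against floating ties). 2 × 2 odds ratios get Woolf (log-scale
Wald) intervals; zero cells get the Haldane-Anscombe +0.5 correction,
flagged. Column collapses are validated to be exact partitions.

The packaged lopinavir-ritonavir tables are described in
`src/trialkit/data/NOTES.md`, including a discrepancy in secondary
literature around the collapsed improvement table that the printed counts
cannot reproduce; this package reports only what the counts imply.

## Synthetic-data generator

`SyntheticConfig`/`generate_trial` realize exactly the structure the
analyses assume: per arm, terminal subjects with probability γ (recorded
as censored at the horizon, the source trials' convention for deaths
before day 28), exponential or Weibull latency with proportional hazards
across arms, administrative censoring at day 28, 1:1 or 2:1 allocation.
The true η is stored in a `truth_eta` side column for recovery tests only.
Randomness: one root seed, per-arm child streams spawned
deterministically; identical config + seed is byte-identical.

Defaults are the recovery-study conditions: 1000/arm, γ = (0.25, 0.40),
exponential latency rate 0.2/day in both arms (HR 1), horizon 28. The rate
was chosen once so that the generator honors the cure model's
sufficient-follow-up assumption — S*(28) = e^{−5.6} ≈ 0.4%, so the
terminal fraction is identifiable and γ̂ recovery is a meaningful check;
with slower latencies the estimand itself shifts to γ + (1 − γ)S*(τ).
Weibull latency exists to create proportional-hazards violations
(motivating the restricted-mean contrasts).

What the generator does **not** emulate: the ordinal clinical scale
underlying the derived end point, dependent or early censoring, covariate
heterogeneity, staggered entry, or digitization noise (emitted curves are
exact KM complements on a grid). Passing recovery tests therefore shows
correctness of the estimators under the model's own assumptions, not
robustness to their violation on real figures.

## Case studies and problem sizes

`run_case_study` reproduces each reanalysis pipeline end to end; with no
user-supplied curve coordinates it generates synthetic stand-ins
(arm sizes 99/100, 158/78, 538/521; per-study plateaus and latency rates)
clearly labelled `synthetic_standin` — their numbers illustrate the
pipeline and carry no information from the real figures. Reports are
sorted-key JSON plus Markdown and regenerate byte-identically from
config + seed.

Problem sizes used by the shipped checks, chosen as desk-scale study
conditions: 50 trials × 1000/arm with 400 bootstrap replicates for
cure-model calibration (coverage pooled over the 100 arm-level
intervals); 2000 bootstrap replicates for projection checks; 10⁷ draws for
the Monte-Carlo cross-check of the inflation quadrature; 20 random
configurations for reconstruction round trips.

## Known limitations

* γ and late latency mass are confounded under administrative censoring
  (see above); the fit assumes, and cannot test, sufficient follow-up.
* Cure-model covariates are limited to the arm indicator; no
  promotion-time cure models.
* Breslow tie handling throughout; reconstructed (heavily tied) data will
  differ slightly from Efron-based fits.
* The bootstrap projection aggregates with mean-log-HR / mean-SE Wald
  intervals; other aggregations are defensible and would change projected
  interval widths.
* No competing-risks estimator: death is modelled as terminal-fraction
  mass, not as a competing state.
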