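# Methods

This note documents the statistical procedures implemented in
`survbenefit`, the assumptions behind them, the defaults and why they were
chosen, and what the synthetic-data results do and do not demonstrate.

## Setting and notation

Data are a randomized trial: for participant *i* we observe follow-up time
Tᵢ > 0, event indicator Cᵢ ∈ {0, 1} (1 = event at Tᵢ, 0 = censored), arm
Zᵢ ∈ {0, 1}, and baseline covariates xᵢ. Missing baseline data are
rejected, not imputed. Two latent survival functions Sᵢ¹(t), Sᵢ⁰(t)
describe each participant's potential outcomes; a model M produces
predictions Ŝᵢ¹(t), Ŝᵢ⁰(t) (or a scalar benefit directly). Individual
benefit is a functional contrast g(Sᵢ¹) − g(Sᵢ⁰) and is never observed —
every metric here works around that by using group-level or pair-level
observable surrogates.

Times are continuous reals in arbitrary units (years throughout the
examples); no unit conversion is performed, so horizons t* must be given
in data units. Benefit on the hazard-ratio scale is deliberately not
implemented: hazard ratios are awkward as causal contrasts and none of the
downstream metrics need them.

## Benefit definitions

Four definitions, all signed so positive = treatment better:

| definition | formula | horizon | scale |
|---|---|---|---|
| SP | Ŝ¹(t*) − Ŝ⁰(t*) | t* | probability |
| RST | ∫₀^{t*}(Ŝ¹ − Ŝ⁰)dt | t* | time |
| ST | ∫₀^∞(Ŝ¹ − Ŝ⁰)dt | — | time |
| PS | t¹(p) − t⁰(p), Ŝᶻ(tᶻ(p)) = p | p ∈ (0,1) | time |

Curve pairs are stored on a shared grid (default: 200 evenly spaced points
from 0 to the maximum observed time). When the producing model is
parametric (Weibull/exponential) the pair carries the linear predictors
and scale, and SP/RST/ST/PS are evaluated in closed form (RST via the
lower incomplete gamma function); otherwise SP interpolates linearly, RST
uses the composite trapezoid on the grid, PS inverts the curve by linear
interpolation, and ST raises — a step curve gives no basis for
extrapolating the tail, and a median-type benefit that the curve never
reaches is masked undefined rather than guessed.

## Nonparametric machinery

Kaplan–Meier is implemented directly (product-limit, right-continuous
steps, events before censorings at tied timestamps) with Greenwood
variance, and RMST as the exact area under the step curve with the
standard large-sample variance Σⱼ Aⱼ² dⱼ/(nⱼ(nⱼ−dⱼ)), Aⱼ the area from
event time j to t*. Agreement with lifelines to ≥10 significant digits is
enforced in the tests. Evaluation beyond a curve's last observation
carries the last value flat and emits `ExtrapolationWarning` instead of
failing — some group-level contrasts are otherwise not estimable at all.

## Reference model: Weibull interaction S-learner

log T = μ + bᵀx + z(g + dᵀx) + σε with ε standard minimum-Gumbel, a single
shared scale σ (no arm-specific scale). The right-censored log-likelihood
is maximized by L-BFGS-B on (μ, b, g, d, log σ) with the analytic
gradient; the coefficient covariance is the inverse numerical Hessian at
the optimum. An optional fixed-scale fit (`fix_sigma=1`) gives exponential
regression, whose intercept-only rate MLE has the closed form
events/total-follow-up used as a test oracle. Rank-deficient designs are
rejected naming the collinear columns (QR with pivoting). Any other
learner plugs into the same evaluation pipeline through the
`fit`/`predict_curve_pair` (or `predict_benefit`) adapter contract; the
metrics are model-agnostic by construction.

## Cross-validation harness

k-fold (default 10), stratified by arm so each training subset keeps the
trial's arm ratio — the design is silent on stratification, but without it
small folds can lose an arm entirely. Exactly one out-of-sample prediction
per participant; the fold provenance is recorded. Out-of-sample predicted
benefit is then a *baseline* variable: splitting on it respects
randomization, which is what makes the calibration and decision contrasts
unconfounded. Tests enforce this mechanically (a memorizing probe model,
and invariance of held-out predictions to permuting held-out outcomes).
External validation bypasses the harness: every metric accepts
pre-computed predictions.

## C-for-benefit

Matched treated–control pairs supply the observable surrogate of benefit:
whichever member has the shorter follow-up determines the pair's observed
benefit (+1 event in control, −1 event in treated, 0 censored; equal times
with two events score 0 — neither is "shorter"). Matching is by rank on
predicted benefit (sort each arm, pair equal ranks) or greedy 1:1
nearest-neighbor without replacement on Mahalanobis distance of
standardized covariates (propensity-score distance available; singular
covariance falls back to Euclidean with a warning). Pair-level predicted
benefit defaults to the mean of the two members' predictions. With
unequal arms, the excess of the larger arm is excluded at random;
exclusion *and* pairing are re-drawn in each of the (default 100)
replicates, and the estimate is the replicate mean. When arms are equal
and matching is by benefit, the matching is deterministic and one
replicate suffices.

Concordance counts pair-of-pair combinations with unequal observed
benefit; the higher-observed pair must have the strictly higher predicted
benefit (prediction ties score ½). The production implementation sorts
within the three observed-benefit classes (O(P log P)); a brute-force
double loop is kept as an exact oracle in the tests. The per-replicate CI
is a normal approximation with a U-statistic (DeLong-style component)
variance, endpoints averaged over replicates; it deliberately excludes
matching uncertainty. C-for-benefit is a pure rank statistic — invariant
to monotone transforms of the predictions, and antisymmetric under sign
flip — both property-tested.

## Calibration-for-benefit

*Grouped*: quantile groups of predicted benefit (sizes equal up to ties);
observed group benefit is the within-group difference of arm-wise KM
survival at t* (SP) or arm-wise RMST (RST), with variance summed across
the independent arms (randomization). a₀ and a₁ come from unweighted OLS
of observed on predicted group means with t-intervals on n_groups − 2 df
(inverse-variance weighting is available but not default — the group
variances are similar by construction and the unweighted line is the
conventional presentation). Bias is grouping-free: whole-sample observed
benefit minus mean predicted benefit. MSE/RMSE average the squared group
discrepancies unweighted. A group with an empty or eventless arm is
flagged and dropped from the regression. `n_groups=1` is a bias-only mode
(slope/intercept undefined); `n_groups=2` is rejected since a two-point
line has no error df. The x-axis "error bars" exported for plotting are
the min–max range of predicted benefit per group.

*Smooth (model-based)*: per participant, p̂ᶻ = log(−log Ŝᶻ(t*)) (survival
clamped to [1e−10, 1−1e−10]); per arm, an auxiliary Cox model (lifelines,
Breslow baseline) with a restricted-cubic-spline basis of that arm's p̂ᶻ —
knots at equally spaced quantiles, 10/50/90% for the default 3 knots — is
fit on that arm's data and then evaluated at t* for *all* participants.
The difference of the two auxiliary predictions is the quasi-observed
benefit plotted against the predicted Ŝ¹(t*) − Ŝ⁰(t*). The auxiliary
models assume proportional hazards in the spline covariate; no relaxation
is implemented. This route requires per-arm curves and is unavailable to
benefit-only models.

## Decision accuracy

Recommendation: treat iff B̂ᵢ > B_Th (default 0; ties go to control —
conservative for a costly intervention; configurable). Crossing
recommendation with received arm gives groups g1…g4; with K(·) the KM
survival (or RMST) at t* of a participant set: PB = K(g1∪g4) − K(g2∪g3),
PBvC = K(g1∪g4) − K(g2∪g4), PBvT = K(g1∪g4) − K(g1∪g3), and
K(g3) − K(g4) is the observed effect in the predicted-harm subgroup. The
identity PBvC − PBvT = K(treated) − K(control) (the unadjusted arm
contrast) holds by construction and is asserted in tests. Prediction
uncertainty is deliberately ignored in the rule — the recommendation uses
the point prediction only. Confidence intervals are participant-level
nonparametric bootstrap percentiles (default B = 1000, seeded); the
bootstrap re-derives the group partition per resample, which correctly
propagates the overlap of g1 between the PBvC/PBvT unions. A closed-form
Greenwood approximation would cover PB's disjoint unions only, so the
bootstrap is the single default for all four contrasts.

## Synthetic-data generator

Covariates: x₁, x₂ ~ N(0,1); x₃ three-level categorical (equal
probabilities, dummy-coded against the first level); x₄ ~ Bernoulli(0.5);
arm ~ Bernoulli(0.5). Event time ~ Exponential(rate) with
log rate = β₀ + βᵀx + z(γ + δᵀx); censoring ~ Uniform(0, c_max), optional
administrative cap. True benefit is closed-form in the two rates, so the
generator doubles as an oracle for every metric.

Frozen defaults: β₀ = −1.25, β = (0.3, 0.3, 0.2, −0.2, 0.3), γ = −0.45,
δ = (0.35, 0.35, 0.2, −0.2, 0.3), c_max = 5.65. The interaction
coefficients were fixed at magnitudes comparable to the main effects;
β₀, γ and c_max were then calibrated once against a 2×10⁶-draw evaluation
so that a 2000-participant trial has, in expectation, 51.1% observed
events, median follow-up 1.298 years, and 70.9% of participants with
positive true benefit. These constants are frozen; they are not re-tuned
per run or per analysis. Note the three calibration targets do not
identify the *scale* of treatment-effect heterogeneity (γ and δ can be
rescaled jointly without changing the positive-benefit fraction); with
these defaults the oracle C-for-benefit of the design is ≈ 0.56, which is
the ceiling any model can reach on these trials.

Scenarios: `paper_default` (above); `null_effect` (γ = δ = 0, every true
benefit exactly zero); `outcome_good_benefit_bad` (strong prognostic main
effects on the visible covariates, but the interaction is driven entirely
by a latent covariate withheld from the returned data — a model fit on
what is visible predicts outcomes well in both arms yet ranks benefit at
chance, the canonical failure mode these metrics exist to expose).

What the generator does *not* emulate: covariate correlation and
measurement error, non-exponential (e.g. ageing) hazards, informative or
administrative-pattern censoring, cluster randomization, missing data.
Passing tests on these data show the estimators are correct under the
stated design, not that any particular clinical model is good.

## Numerical choices and degenerate inputs

- Optimizer tolerance: L-BFGS-B gtol 1e−10; a fit is accepted if the
  scaled gradient norm is small even when the line search reports
  convergence pedantically.
- cll clamp 1e−10; spline knots must be distinct or the smooth
  calibration raises; arms need more events than spline df.
- Grid default 200 points to the maximum observed time; RST trapezoid
  error is O(h²) (property-tested).
- Constant predictions: calibration slope undefined → error; C-for-benefit
  all-ties → 0.5; decision rule still well-defined.
- Zero comparable pair-of-pairs → C-for-benefit flagged undefined, not 0.5.
- Bootstrap resamples that empty a union contribute NaN and are dropped
  via nan-percentiles.

## Problem sizes used in the shipped analyses

The test suite and acceptance script use n = 2000 trials (20 seeds for
generator marginals, 10 seeds for the cross-validated Weibull analysis,
100 matching replicates throughout), n = 5000 for parameter recovery, and
a single n = 20000 draw for large-sample calibration recovery — sizes at
which Monte-Carlo error is small relative to the effects being checked
while a full run stays in the order of seconds to minutes.

## Known limitations

- The C-for-benefit CI ignores matching uncertainty (the replicate spread
  is reported alongside); a participant-level bootstrap including matching
  is available but slow.
- Smooth calibration inherits the auxiliary models' proportional-hazards
  assumption and is undefined for benefit-only models.
- PBvT/PBvC intervals are percentile bootstrap; no analytic standard
  errors are provided.
- The generator's effect-heterogeneity scale is a design choice, not a
  calibrated quantity; discrimination levels measured on it depend on that
  choice (see the generator section).
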