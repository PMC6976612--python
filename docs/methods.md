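# Methods

This note documents the models, parameter choices and numerical
conventions behind `vchinrest`, and what the simulations can and cannot
say about real data.

## Geometry

All internal computation is in millimetres and degrees; pixels appear
only at I/O boundaries, converted through the logical pixel density
(LPD = card image width / 85.60 mm). Angles are mapped to on-screen
extent with the exact tangent rather than the small-angle
approximation: at the 13.5° calibration angle the small-angle error is
already ~2%, which would bias every distance estimate. The screen is
modelled as flat and perpendicular to gaze at fixation; peripheral
stimuli are placed by tangent projection with no off-axis correction,
so extents quoted "in degrees" are exact only along the horizontal
meridian through fixation.

Viewing distance follows d = s/tan(α) with α = 13.5° by default — the
blind spot's *entry* point, roughly half the 4.5° blind-spot diameter
nearer fixation than its ~15.8° center.

## Blind-spot sweep model

The simulator reduces a sweep to its measurable outcome: the keypress
offset. Each trial's offset is `true_d · tan(entry_angle)` plus
Gaussian keypress noise with SD 2 mm on screen (position noise, not a
latency model — no sweep speed is modelled, so reaction-time delays
fold into the same term). Offsets are unsigned magnitudes and clamped
positive. Estimation averages all trials; no outlier rejection is
applied.

Population entry angles are truncated-normal, mean 13.59°, SD 0.96°,
range [11.53°, 16.01°]. Because estimation fixes α = 13.5° while true
entry angles center on 13.59°, estimated distances carry a small
multiplicative bias of tan(13.59°)/tan(13.5°) ≈ 1.007 — about +0.4 cm
at a 53 cm seat, which the validation-style simulations reproduce.

## Staircase

The 1-up 3-down rule: any error multiplies the spacing by the step
factor (default 1.2); three consecutive correct responses divide it by
the same factor and reset the counter (which also resets on any error).
Steps are multiplicative — constant in log spacing — because critical
spacing spans a multiplicative range; no step-size shrinking schedule
is used. Spacing is clamped, never terminated, at [1°, eccentricity]
(flanker diameter below; flankers would cross fixation above). A
reversal is recorded at the trial where the step direction flips; the
first direction change is the first reversal. The threshold is the
geometric mean of the last 6 reversal spacings (arithmetic selectable),
requiring at least 2 reversals; with fewer, estimation fails carrying
the partial state — in cohort runs such blocks are recorded as NaN and
excluded listwise with a count, mirroring per-analysis exclusions in
real deployments.

The equilibrium accuracy of a 1-up n-down rule is 0.5^(1/n): the track
is stationary where a down-step (n straight corrects, probability pⁿ)
is as likely as an up-step, i.e. pⁿ = ½. For n = 3 that is 0.7937; a
2000-trial simulated run reproduces it within a percentage point.

A deliberately documented property of the *deployed* 25-trial design:
the track starts at 1.3 × eccentricity/2, above most observers'
thresholds, and short tracks yield 5–8 reversals, so the last-6-
reversal estimator retains part of the initial descent. The measured
threshold therefore overshoots the latent critical spacing by ≈ +0.15°
at 4° and ≈ +0.21° at 6° under default observers. This bias is treated
as part of the instrument, not removed.

## Observer model

Crowding responses come from a 2AFC Weibull in log spacing:
p(s) = ½ + (½ − λ)·F(s), F(s) = 1 − (1 − F*)^((s/c)^β), with guess
rate fixed at ½ (gap up vs down), lapse λ ∈ [0, 0.06], slope β, and
critical spacing c. F* is chosen so that p(c) = 0.5^(1/3) exactly when
λ is at its 0.01 default — "critical spacing" is thereby operationally
the spacing the staircase converges to, making threshold recovery a
well-posed identity rather than a convention mismatch.

Latent critical spacing is
`c(e) = e·bouma_ratio + dyslexia·0.26° + a·(age − 26)²`.

Generator defaults (one cohort, chosen once):

| parameter | default | rationale |
|---|---|---|
| bouma_ratio | N(0.38, 0.08) trunc [0.15, 0.75] | calibrated (below) |
| dyslexia prevalence / effect | 6% / +0.26° | reference cohort regression estimate |
| age | N(26.3, 12.4) yr trunc [7, 71] | reference cohort demographics |
| age curvature a | 2.5×10⁻⁴ °/yr² around vertex 26 yr | see below |
| blind-spot entry | N(13.59°, 0.96°) trunc [11.53°, 16.01°] | observed distribution |
| seating distance | N(473, 89) mm trunc [174, 683] | observed online range |
| drift SD | 44 mm per phase | see below |
| lapse / slope | U(0, 0.02) / N(3.5, 0.5) trunc [2, 5] | standard 2AFC values |

**Bouma-ratio calibration.** The package's defining calibration is that
the *full pipeline* (generate → sessions → staircases → summarize)
reproduces cohort mean crowding of ≈ 1.61° at 4° and ≈ 2.66° at 6°.
Those two means imply an eccentricity-increasing measured ratio
(0.40 vs 0.44), which a single latent ratio through the origin cannot
match exactly; after accounting for the staircase's measurement bias, a
latent mean of 0.38 balances the residual errors at ±0.11°, within the
staircase's step resolution. The calibration was run as a dedicated
simulation sweep (3 × 1500 sessions per eccentricity per candidate) and
then frozen.

**Age curvature.** A raw-year quadratic of 0.004 °/yr² would predict
+8° of crowding at the age extremes — beyond the display-bounded
maximum threshold — so the curvature is set to 2.5×10⁻⁴ °/yr², about
+0.5° from the vertex to age 71, the magnitude of the elevation
reported for children and older adults relative to young adults. The
OLS recovery machinery is exercised against larger curvatures in tests
with explicitly-set generator values.

**Distance drift.** Phase-to-phase movement is i.i.d. Gaussian per
blind-spot phase. The target within-subject SD of the three estimates
is ≈ 39 mm; since E[sample SD of 3 draws] = 0.8862σ, the drift SD
default is 44 mm. Keypress noise adds ≲ 5 mm in quadrature and is
neglected in this calibration.

## Session orchestration

Sessions replay the deployed order: calibration → 5-trial blind-spot
(pre) → 5 practice trials → block 1 (25 trials) → 3-trial blind-spot
(mid) → block 2 (25 trials) → 3-trial blind-spot (post). Stimulus
geometry is computed once from the *pre*-phase distance estimate and
not re-calibrated mid-session. True distance is piecewise-constant per
phase; block 1 is presented at the pre-phase distance, block 2 at the
mid-phase distance.

Two frames are tracked separately: *intended* degrees (computed from
the estimated distance; staircase bookkeeping and reported thresholds)
and *presented* degrees (what the physical stimulus subtends at the
true distance; observer responses). If the estimate is k× the truth,
tan(presented) = k·tan(intended) — the simulator asserts this without
conflation, reproducing how calibration error propagates into reported
thresholds in a real deployment.

Per-session accuracy is the fraction correct over the 50 main trials;
practice is excluded. Cohorts derive per-observer seeds by
`SeedSequence.spawn` from a master seed, so runs are reproducible and
one observer's stream never depends on another's.

## Analyses

Cohort summaries report cell means/SEMs by eccentricity and by
dyslexia × eccentricity, the ratio of mean crowding to eccentricity,
distance distribution and reliability. ICC is the one-way
random-effects, absolute-agreement form
ICC(1) = (MSB − MSW)/(MSB + (k−1)·MSW), returning an explicit
undefined marker (`None`) for zero-variance tables. Group comparisons
report both Welch's t and the Mann-Whitney U with a documented
normality advisory (D'Agostino–Pearson per group at n ≥ 20; below
that, the advisory defers to the non-parametric test). The age model
is ordinary least squares on per-session crowding effects
(`crowding ~ eccentricity + dyslexia + age + age²`, eccentricity
numeric): with one threshold per participant-session a participant
random effect is not identifiable, so a mixed model would be
over-specified here.

## Problem sizes

The shipped simulations use 2000 trials for convergence checks, 19
observers × 5 sweeps for the fixed-distance validation analogue, and
500–1000-observer cohorts (two 25-trial staircases each) for the
pipeline calibrations and recoveries; these sizes put Monte-Carlo error
well inside the assertion tolerances while keeping any run under a
minute.

## What the synthetic cohorts do not show

The generator emulates the *structure* of real data, not its full
messiness: no left/right asymmetries, no reaction-time or attention
dynamics, no display heterogeneity beyond the card calibration, no
mid-block posture drift, lapses independent of fatigue, and dyslexia as
a clean additive shift rather than a heterogeneous syndrome. Passing
pipeline tests therefore demonstrate that the estimators are unbiased
and well-calibrated *under the stated model*; empirical quantities that
depend on real participants (absolute distance errors of a few cm,
test-retest ICC ≈ 0.88, specific U statistics) can be computed by the
same machinery but are not reproduction targets.
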