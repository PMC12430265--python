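# Methods

This note documents the models, conventions and design choices behind
`pbdi`: what the synthetic cohort emulates, how the indices are computed,
what the survival machinery assumes, and what the tests do and do not
establish about real data.

## Synthetic cohort model

The generator (`pbdi.synthetic_cohort`) emulates a two-site community
cohort of adults aged 40–69 followed for up to 18 years with two dietary
assessments four years apart.

**Participants.** Age is truncated-normal with mean 52.0 and SD 8.8 years
on [40, 69]; 52.4% are female and 51.8% urban; income and education are
4-level ordinals; BMI is truncated-normal (24.6 ± 3.1 kg/m²); physical
activity is gamma-distributed with mean ~24 METs/day; hypertension
prevalence is 31% and family history of CVD 15%. Pack-years are
constructed literally as packs/day × years smoked for generated smokers,
so the defining identity holds in the data, not just in documentation.

**Dietary exposure.** Each of the 17 food groups has log-normal
servings/day (log-scale SD 0.6 by default) with group means chosen so that
class totals approximate a Korean middle-aged cohort (~12 servings/day of
healthful plant foods, ~8 of less-healthful plant foods, ~3.7 of animal
foods). Total energy is log-normal (mean 1920 kcal/day, log-SD 0.25), and
group intakes scale with (energy/1920)^0.5, giving the positive
intake–energy correlation that makes residual adjustment meaningful. A
configurable fraction (default 1.1%) of participants receives implausible
energy (<500 or >5000 kcal/day) to exercise the exclusion cascade. Wave-2
intakes correlate with wave 1 at ρ = 0.7 on the log scale — in the range
reported for FFQ reproducibility over several years — and a wave-2 record
is missing with probability 0.15 by default.

**Outcomes.** Each cause with a planted effect (CHD, stroke, other CVD)
gets an exponential event time with hazard

  λᵢ = λ₀ · exp(β_q(i) + Σ_c β_c x_ic),

where β_q are the planted quartile log hazard ratios (quartile 1 = 0) on
the participant's *true* quartile — computed by the generator's own
scoring pass on the wave-1 exposures — and the covariate terms use
cohort-mean-centred continuous covariates. Dropout and non-CVD death are
independent exponentials (defaults 0.04/yr and 0.004/yr); administrative
censoring occurs at 18 years; the first occurring cause terminates
follow-up. The default dropout rate was solved so mean follow-up is
~12.8 years, the person-time per participant implied by ~99,750
person-years over 7820 participants. An optional Weibull shape warps event
times while preserving hazard proportionality. Event times are continuous;
the biennial interview grid of real cohorts is deliberately not imposed,
since the analysis operates on person-years.

`calibrate_baseline_hazard` solves, by one-dimensional root finding on the
closed-form expected count E = Σᵢ λ_ci/Λᵢ (1 − e^{−Λᵢ T}), for the common
multiplier on the baseline hazards that yields a target number of events —
the same closed form the generator tests use as an independent oracle.

**What the generator does not emulate.** Joint covariate dependence
(diet–covariate confounding is absent unless planted), item-level FFQ
structure, secular dietary trends, interval censoring, and informative
dropout. Passing recovery tests therefore demonstrates correctness of the
scoring and inference machinery under the stated generating model, not
robustness to confounding or measurement structures the generator lacks.

## Exclusion cascade

Exclusions are applied in a fixed order — missing wave-1 FFQ, energy
outside [500, 5000] kcal/day, baseline CVD/cancer, no follow-up after
baseline, missing covariates — with each participant tallied at the first
criterion met, so tally + retained always partitions the input cohort.

## Index construction

Residual adjustment fits, per food group, an OLS regression of
servings/day on energy across the scoring population and replaces raw
intake with residual + prediction at mean energy (equivalently
raw − b·(energy − mean energy)). The group mean is preserved exactly and
the adjusted values are exactly uncorrelated with energy. Adjusted intakes
may be negative; scoring uses ranks, so no floor is applied. Constant
energy (no regression identifiable) passes raw intakes through.

Quintile cutpoints are the 20/40/60/80 sample percentiles with **linear
interpolation between order statistics**, and cutpoint intervals are
left-open/right-closed with the lowest interval closed. These two
conventions are fixed and echoed into output headers because no standard
nomenclature pins them down, and they determine results bit-for-bit.
Equal adjusted values always receive equal scores; with integer-valued
scores ties are ubiquitous, so the same convention at the quartile stage
(25/50/75 cutpoints) means quartile sizes are generally unequal — tied
totals never split across quartiles.

Scoring populations: quintiles and quartiles are computed on the
post-exclusion analysis cohort, separately for the baseline-segment
exposures and for the cumulative-average segment, both through the same
code path. The per-quartile median total feeds the trend test.

## Person-time and Cox analysis

Each participant contributes up to two counting-process rows split at the
wave-2 date, each carrying its segment's quartile and total; the event
indicator sits on the terminal row. Subtype analyses treat competing
subtypes as censoring (cause-specific hazards). The time scale is
follow-up time with age as a covariate. Estimation uses
`statsmodels.duration.hazard_regression.PHReg` with Efron tie handling and
delayed entry; fits with non-finite or exploding coefficients raise
`ConvergenceError` rather than returning silently. One boundary detail:
statsmodels includes a subject whose entry time exactly equals an event
time in that risk set, whereas R's `survival` does not; with continuous
event times this is a measure-zero discrepancy, and the test suite pins
agreement with R to 1e-6 on a fixture without such coincidences.

The trend test replaces quartile indicators with the per-quartile median
score as one continuous covariate and reports its Wald p-value. The
restricted cubic spline uses Harrell's three-knot basis (knots at the
10/50/90th percentiles; one nonlinear term, linear beyond the boundary
knots, normalised by (k₃−k₁)²); nonlinearity is the likelihood-ratio test
of spline vs linear-only, linearity the Wald test of the linear term; the
curve is referenced to the median total, where it is exactly zero. Knot
collapse under massive ties reduces to the linear fit with a warning.

The proportional-hazards test is the Grambsch–Therneau score test computed
from Schoenfeld residuals on the counting-process risk sets, with the
exact profiled information (Σg²V − (ΣgV)(ΣV)⁻¹(ΣgV)) rather than the
classical averaged-V approximation; it reproduces R `survival::cox.zph`
(identity transform) to 1e-6 on the reference fixture. Effect-modification
tests add product terms of the centred trend variable with one modifier at
a time (age band, sex, family history, median-split physical activity, BMI
band, ever-smoking, hypertension) and compare the joint Wald p-value to
0.05/7; sparse BMI bands (<20 observations) are dropped to avoid
separation. The early-event sensitivity analysis removes *all* person-time
of participants whose event occurred inside the window, matching the
convention of reporting a reduced case count; early-censored participants
are retained.

## Parameter-recovery experiments

The recovery experiments (`pbdi.recovery`) plant a quartile hazard-ratio
profile and ask the full scoring + Cox pipeline to give it back. Because
planted effects act on the generator's true quartiles, recovery cohorts
are generated *clean* — no data defects, wave-2 collection disabled so
wave 1 is carried forward — at n = 7820. The analysis-stage quartiles then
coincide with the planted ones and the median fitted extreme-quartile HR
estimates the planted HR without attenuation from exposure
misclassification. With the default two-wave noise switched on instead
(as in the README example), the fitted HR is biased toward the null, which
is the classical and expected consequence of nondifferential exposure
measurement error. Baseline hazards are calibrated once per design to the
target event count (~314 CHD, ~287 stroke, ~597 composite CVD); the
composite experiment spreads the planted profile across all three
cause-specific hazards (0.50/0.45/0.05) so the composite hazard carries
the same proportional structure.

## Numerical and testing choices

Seeds enter through `numpy.random.default_rng([seed, stream])`, giving
byte-identical tables per config and independent streams per stage.
Null-calibration tests run 200 replicates of a 400-participant cohort
(~90 events each) and require empirical rejection in [0.02, 0.08] at
nominal 0.05 for the trend, nonlinearity, PH and interaction tests; power
tests use planted violations sized to give ≥80% (time-varying effect:
quartile log-HRs (0.6, 0.9, 1.2) doubling after year 9 at ~700 events;
quadratic log-hazard 0.3·z²; sex-by-trend interaction 0.08 per score
point) so that pass/fail is informative at modest replicate counts.
Replicate counts and cohort sizes throughout the suite are the smallest
that leave comfortable Monte-Carlo margins around each asserted bound.

## Known limitations

Cause-specific censoring is the only competing-risk treatment offered (no
subdistribution hazards); missing covariates are excluded, not imputed;
the taxonomy assigns each item wholly to one group, so mixed dishes are
not decomposed; and the generator's covariates are mutually independent,
so adjusted and unadjusted models differ only through planted covariate
effects on the hazard.
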