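# Methods

## Workload arithmetic

A unit-day's establishment is the census-weighted mean multiplier times the
administrative 07:00 patient count.  The two counts are kept distinct on
purpose: the shift leader's per-level census defines the acuity mix, the
administration system's count defines the volume, and multiplying the mean
weight by the administrative count guards against patients omitted from
shift-leader reports.  An all-zero census with a nonzero administrative
count is an error (no mean weight exists), not a zero.

Converting an establishment to daily care hours divides by 1 + uplift and
multiplies by weekly hours / 7.  Division by 1.22 — not multiplication by
0.78 — because the uplift is added on top of the base requirement, so
removing it must invert that multiplication exactly (the round-trip
establishment → hours → establishment is an identity to 1e-9).

Specialing (one-to-one supervision) adds 24 h per flagged patient-day to a
*daily* requirement but never to an establishment estimate: the enhanced
care that drives specialing was part of the observations behind the
multipliers, so adding it again at establishment level would double count.
The specialing hours are split between registered nurses and assistants by
the unit's planned skill mix, like all other required hours; the data give
no basis for assigning them to one staff group, and the split is a config
key (`specialing_hours_per_patient_day`, default 24).

The planned skill mix itself is proxied by the unit's average observed RN
share of deployed hours, computed per unit over the whole year unless a
mix is supplied.

Shortfall is required − deployed per patient-day: positive = understaffed.
Days with zero patient-hours have no defined HPPD and are excluded with a
logged warning rather than imputed.

The five default multipliers (0.99, 1.39, 1.72, 1.97, 5.96 WTE/patient for
levels 0, 1a, 1b, 2, 3) are tool constants shipped as editable configuration
(`config/multipliers.yaml` mirrors them); nothing in the package depends on
there being exactly five levels.

## Bootstrap precision of audit estimates

An audit of n days estimates the establishment as the mean of n daily
values.  We resample n days iid with replacement from the unit's full daily
series (1000 resamples by default), take each resample's mean, and report
the 2.5/97.5 percentile interval of those means (linear interpolation
between order statistics; a normal-approximation interval is available as
`method="normal"` and agrees within a few percent).  Precision is half the
CI width as a percentage of the mean; for a zero-mean series it is
undefined and reported as missing.

The iid bootstrap deliberately ignores serial correlation — an audit samples
days, not blocks — so the reported precision describes the audit design, not
a time-series forecast.  Units whose series is shorter than n are ineligible
at that audit length and drop out of that row's averages, which is why the
unit count can fall as n grows.  Threshold counts use CI width ≤ 1 and ≤ 2
WTE inclusively (±0.5 and ±1 staff member around the mean).

## Cleaning and linkage

* One acuity rating per unit-day: the earliest of the day, so a later rating
  substitutes automatically when the morning one is missing.
* Shortfall outliers: days outside mean ± 3 SD of the unit's own shortfall
  distribution are removed (both partitions are returned for audit).  The
  rule is per unit because its purpose is catching periods when *that ward*
  was not functioning normally; on clean Normal data it removes ≈ 0.27%.
* Units that change beds, specialty or location mid-year are split into
  separate derived units (`W1/a`, `W1/b`, ...); segments shorter than 28
  days are dropped as too short for even the minimum 20-day audit row.
* Reverse-coded units: some units consistently entered 0 for yes and 1 for
  no on all three adequacy questions.  Inverting every answer preserves all
  pairwise associations between the responses, and the day-level association
  between responses and shortfall is far too weak (|r| ≈ 0.03 at realistic
  effect sizes) to test sign reliably, so detection votes on *rate
  direction*: a unit is flagged when at least two of its three response
  rates sit on the opposite side of 0.5 from the fleet median (typical rates
  are ≈ 0.78 yes for "enough staff" and ≈ 0.05 for the two negatively
  phrased questions).  An honestly struggling ward can cross 0.5 on "enough
  staff" alone but essentially never on the other two, so it casts at most
  one discordant vote.  Flagged units have all three binaries inverted; the
  recode is an involution and units with under 30 responded days are left
  alone with a warning.
* Linkage: the microsurvey answered on the morning of day d+1 reports on
  the 07:00–07:00 window that began on day d, so responses join at
  response-date − 1.  Days without a response keep their covariates and are
  dropped listwise by the modelling stage; no imputation.

## The adequacy model

For each outcome y (enough staff / care left undone / breaks missed):

    logit P(y=1) = β₀ + β·x + b_unit + b_hosp,   b ~ N(0, σ²) per level

with covariates in natural units (per HPPD, per proportion — odds ratios
are per natural unit, nothing is standardised): RN shortfall, NA shortfall,
turnover per staff hour, surgical (vs medical/mixed), proportion single
rooms, and day-of-week indicators with Monday as reference.

Estimation is maximum likelihood under the Laplace approximation.  Random
effects are spherical (b = σu); an inner penalised IRLS Newton loop
maximises the joint penalised likelihood over (β, u) — exploiting the
indicator structure of the random-effect design, so an iteration is
O(n·k²) in the fixed effects only — and a Nelder–Mead search over the two
standard deviations minimises the profiled Laplace deviance
`dev + log det(I + S Z′WZ S)`.  This is the standard mixed-model scheme;
on full-scale data it agrees with lme4's `glmer` to four decimals on the
variances and log-likelihood, and with both variances at zero it collapses
exactly to ordinary logistic regression.  With the cluster sizes here
(hundreds of days per unit) the Laplace approximation is effectively exact,
so no quadrature upgrade is fitted.

Standard errors are Wald, from the fixed-effect block of the inverse
penalised Hessian at the optimum (conditional on the variances, as mixed-
model software reports); p-values are Wald z-tests.  AIC/BIC use
k = fixed effects + 2 variance parameters and n = day-level observations.
Complete separation is detected as an absurd effect per SD of a covariate
(> 10 on the log-odds scale) and raised as an error naming the covariate;
non-convergence flags the result rather than silently returning.

Variance partition coefficients use the latent-variable formulation with
the day-level logistic residual fixed at π²/3, and both levels are reported
over the same total σ²_unit + σ²_hosp + π²/3 (non-cumulative).  This is the
interpretation under which the variance pair (1.097, 0.598) maps exactly to
the share pair (0.220, 0.120) used as the generator default.

Model comparison: quadratic shortfall terms and candidate interactions are
added one at a time and judged by Wald significance and ΔAIC/ΔBIC; when the
two criteria disagree the comparison is reported as "ambiguous" rather than
resolved by fiat.  The effect curve reports exp(β₁x + β₂x²) relative to
zero shortfall with a delta-method band.

Sensitivity variant: `--exclude-hospital` refits without one hospital; if
one hospital remains the hospital level is dropped with a warning.

## Synthetic fleet generator

The generator is first-class, tested code; its defaults *are* the study
conditions rather than tuning knobs.

**Fleet**: 4 hospitals × 20 units, 365 days from 2017-01-01.  Beds uniform
20–35 (fleet total ≈ 2200), occupancy ≈ N(0.79, 0.05), 35% surgical,
single-room proportion Beta(2, 4), planned skill mix ≈ N(0.56, 0.08).

**Workload**: each unit draws a mean weighted multiplier ≈ N(1.64, 0.12)
and an establishment CV from Gamma(shape 4, mean 9.4%).  The identities
behind those two numbers: mean census 21.3 × mean multiplier 1.64 ≈ 35 WTE
establishment, whose implied requirement is 35/1.22 × 37.5/7 / 21.3 ≈ 7.2
HPPD; and a 20-day audit of a series with CV c has expected precision
1.96·c/√20, which equals 4.1% at c = 9.4% with CI width ≈ 2.9 WTE at a
35 WTE mean.  Day to day, the patient count and the mean multiplier
fluctuate log-normally (CV split 0.6/0.8 between them), and integer level
counts are composed by a vectorised greedy search whose residual error on
the weighted mean is ~0.1% — far below the planted variation.  Patient-hours
are 24 × count; admissions/discharges are Poisson at a rate giving turnover
≈ 0.042 patients per staff hour; specialing is Poisson(0.15) per unit-day.

**Staffing**: deployed = required − shortfall × patient-days, floored at 0.
RN and NA shortfall components are drawn independently with means split by
the skill mix w and variances apportioned by it (RN ~ N(0.1w, 0.9√w), NA ~
N(0.1(1−w), 0.9√(1−w))), so their sum is exactly N(0.1, 0.9) HPPD while the
two covariates remain separately identifiable — a deterministic split by w
would make them perfectly collinear within unit and destroy the RN/NA
distinction the models estimate.

**Outcomes**: unit and hospital intercepts are drawn from their planted
variances (1.097 and 0.598), the fixed coefficients are the study's
adjusted odds ratios on the log scale, and each outcome's intercept is
solved by root-finding so the fleet's marginal rate is exactly 0.78 / 0.05 /
0.05 in expectation.  The three outcomes are sampled independently given
the linear predictor — they are modelled separately, so cross-outcome
correlation beyond the shared predictor is deliberately not modelled (a
known limitation: real "enough staff" and "care left undone" answers from
the same nurse are likely residually correlated).  Responses are stamped the
following morning.  Optional contaminations: reverse-coding injection
(invert all three binaries for chosen units), morning-assessment removal at
4% and response removal at 15% (the observed completeness rates), each
recorded in a `truth.json` sidecar so cleaning tests are self-verifying.

What the generator does **not** emulate: individual patients and lengths of
stay (the unit-day is atomic), serial correlation in censuses, seasonal
structure, inter-rater error in classifications, or systematic differences
between shift-leader and administrative counts.  Passing tests therefore
show that the pipeline recovers what it assumes, not that real wards satisfy
those assumptions.

## Numerical and testing choices

* All randomness flows through `numpy.random.SeedSequence`; a master seed
  expands into per-stage seeds in a fixed order, so stages are individually
  reproducible and the whole pipeline is bit-identical under a repeated
  seed.
* Nelder–Mead tolerances: 1e-3 on the standard deviations, which bounds the
  variance error well below the VPC tolerances of interest; the final solve
  restarts cold at the optimum for run-to-run determinism.
* Recovery testing uses replicate fleets.  Per-term checks across a family
  of fixed effects use a Bonferroni-adjusted threshold (a plain 2-SE check
  on 11–33 unbiased estimates fails some term by chance about half the
  time); the headline staffing terms are additionally held to plain 2 SE.
* Estimating a hospital-level variance from 4 hospitals is intrinsically
  poor: ML sees only the realised spread of 4 draws (expectation ¾ of the
  planted variance about the fitted mean) and unit-level covariates absorb
  part of the rest, so recovered hospital VPCs average ≈ 0.06–0.09 against
  the planted 0.12. lme4 reproduces the same numbers; this is a property of
  the design, not the fitter.
* Analysis scripts run at the study scale (~29k unit-days, ~24k with
  outcomes); the acceptance script averages model coefficients over 50
  replicate fleets — its own variance-reduction choice, reported as such.
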