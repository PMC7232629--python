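# wardstaff

Tools for evaluating acuity-based nurse staffing requirements on hospital
wards: how precisely a ward's staffing *establishment* can be estimated from
audits of daily patient classifications, and whether shortfalls against the
tool-implied requirement predict nurses' own judgements that staffing was
inadequate.

## The problem

Most English acute hospitals size ward nursing establishments with a patient
classification tool: each day every patient is assigned one of five
acuity/dependency levels, each level carries a multiplier m_l (whole-time-
equivalent staff per patient), and the ward's required establishment for that
day is

    E = ( Σ_l n_l · m_l / Σ_l n_l ) · N

where n_l are the shift leader's per-level counts and N is the 07:00 patient
count from the administration system.  The multipliers already include a 22%
*uplift* for leave and sickness, so the daily care hours implied by an
establishment are `E / 1.22 × 37.5 / 7` (37.5 contracted hours per WTE-week),
plus 24 h for each patient requiring one-to-one supervision ("specialing")
when a single day's requirement is wanted.  Shortfall for a day is required
minus deployed hours, expressed per patient-day (HPPD, patient-hours/24);
positive means understaffed.

The package answers two questions about this procedure:

1. **Precision** — a guideline audit observes a ward for 20 days.  How wide
   is the 95% CI of the establishment estimated from n audit days?  We
   bootstrap audits of n days (1000 resamples) from each ward's daily
   establishment series and report precision = half the CI width as a % of
   the mean.
2. **Validity** — do shortfalls predict the shift leader's next-morning
   reports (enough staff for quality / care left undone / breaks missed)?
   We fit three-level logistic models, day nested in unit nested in
   hospital, with random intercepts at unit and hospital level (Laplace
   maximum likelihood; latent-variable variance partition coefficients with
   day-level residual π²/3).

Because ward-level staffing data are confidential, the package ships a
calibrated synthetic fleet generator (4 hospitals × 20 units × 365 days,
mean census 21.3, mean weighted multiplier 1.64 → mean establishment ≈ 35
WTE, requirement ≈ 7.2 HPPD, adequacy rates 78%/5%/5%) with contamination
injectors (reverse-coded response units, missing assessments) that the
cleaning rules must catch.  All analyses run end-to-end on that generator;
recovering the planted parameters through the full pipeline is the test of
correctness.

## Worked example

```sh
python analysis/01_simulate.py     # write the synthetic fleet
python analysis/02_precision.py    # audit-length sweep
python analysis/03_adequacy.py     # multilevel adequacy models
```

The precision sweep prints (seed 0):

```
 n_days  avg_ci_width_wte  avg_precision_pct  n_units_width_le_1  n_units_width_le_2  n_units
     20              3.11               4.45                   4                  21       80
     40              2.20               3.16                   8                  37       80
    ...
    180              1.04               1.48                  40                  77       80
```

— a 20-day audit pins a ~35 WTE establishment to a ~3 WTE wide interval
(precision ~4%); even 180 days leaves half the wards outside ±0.5 WTE.  The
adequacy stage prints:

```
enough_staff: RN shortfall OR 0.88 (-12% odds per HPPD), VPC unit 0.24 / hospital 0.09, AIC 20839
care_left_undone: RN shortfall OR 1.08 (+8% odds per HPPD), ...
quadratic comparison (care left undone): dAIC +3.7, dBIC +19.8, preferred: linear
```

— each hour-per-patient-day of registered-nurse shortfall lowers the odds of
a "enough staff for quality" report by ~12% on this realisation (the
generator plants −11%), with no evidence of a threshold at the recommended
level.  A single command runs everything and writes a markdown report with
the tables and figures:

```sh
wardstaff run-all --seed 0 --outdir results/run
```

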