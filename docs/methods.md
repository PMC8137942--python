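# Methods

## Model structure

The analysis couples a one-time screening decision tree to a monthly-cycle
Markov cohort model with a lifetime horizon (480 cycles ≈ 40 years from
the cohort mean age of 59.59, i.e. to about age 100; overridable).

**Decision tree.** Each of three arms screens the same cohort of 1000
chronic-bronchitis patients once: no screening (usual care), a screening
questionnaire (sensitivity 87.5 %, specificity 38.8 %, ¥8/test), or a
portable spirometer (99.9 %/97.7 %, ¥34/test). The tree uses
expected-value cohort arithmetic, not sampling. Screen positives undergo
confirmatory diagnostic spirometry (¥220), assumed perfectly accurate —
spirometry is the diagnostic gold standard — so false positives are ruled
out and return to the non-COPD state. COPD prevalence among CB patients
is 31.37 %, split 31.38 / 46.04 / 22.58 % across mild / moderate /
severe-very severe. True positives enter the Markov model *detected*,
false negatives *undetected*; with no screening every COPD patient enters
undetected.

**Health states.** Non-COPD; detected and undetected mild, moderate, and
severe/very severe COPD; absorbing death. Undetected patients may stay,
progress, become detected, or die; detected patients may stay, progress,
or die. Severity never regresses and detection never reverts.

**Lung-function engine.** Severity is not a free transition probability:
each sub-cohort carries a deterministic trough-FEV1 trajectory and is
relabelled whenever the trajectory crosses a sex-specific GOLD boundary
(tunnel semantics). Predicted FEV1 uses the sex-specific Chinese
reference equations in ln(height) and ln(age); the equations' age-spline
term is a single scalar per sex, calibrated in closed form so that 80 % of
predicted FEV1 at the base cohort (155.8 cm female / 167.1 cm male, age
59.59) equals the published mild-to-moderate boundary (1.77 L / 2.44 L).
The two sexes' calibrated values agree to 4 × 10⁻⁴, confirming the four
published boundaries are mutually consistent under one shared spline
value. The spline is frozen at its base-cohort calibration, so one-way
perturbations of height and age shift predicted FEV1 and all boundaries,
which is what makes height an influential parameter. Sub-cohorts enter at
the midpoint of their grade (90 / 65 / 25 % of predicted). Detected
trajectories rise by the treatment effect for 6 months with decline
suspended, then decline at 0.041 L/year ÷ 12; undetected trajectories
decline from the first cycle. FEV1 floors at zero. Threshold crossing
uses "first integer cycle strictly below the boundary". A single decline
rate is applied to every severity because only one value is published;
per-severity overrides are a config field.

**Late detection.** Undetected sub-cohorts convert to detected at
severity-specific monthly probabilities (annual 20 / 50 / 90 % via the
exponential conversion), pay the ¥220 confirmation fee at that cycle, and
switch from chronic-bronchitis treatment (¥288/month) to COPD drug and
maintenance costs. **By default late-detected patients do not receive the
6-month FEV1 improvement window** — the improvement belongs to patients
detected at screening entry, matching the two-trajectory (detected vs
undetected) lung-function illustration that defines the model. This is a
deliberate structural choice: if the window were granted at any detection
time, every COPD patient would eventually receive the same one-off FEV1
bump, the arms' lung-function paths would converge, and screening could
never be cost-saving — the questionnaire arm would cost *more* than usual
care, contradicting the study's central finding. The alternative reading
is available via `Settings.late_detection_effect = True`.

**Treatment mix.** Prescribing by severity is a first-class config field:
mild = LAMA alone; moderate = ½ LAMA alone + ½ LABA+ICS; severe = equal
thirds LABA+LAMA, LABA+ICS, triple therapy. Drug costs and FEV1 effects
are mix-weighted, i.e. the mix is treated as one blended regimen for both
the cohort engine and the microsimulation (expected cost ¥253 / ¥183.5 /
¥374 per month; effect 0.022 / 0.0265 / 0.0273 L/month).

**Events.** Each cycle, living COPD sub-cohorts face a monthly
exacerbation probability (annual 19 / 19 / 26.5 % converted by
`1 − (1 − p)^(1/12)`), split into hospital-treated (68.42 / 68.42 /
66.04 %) with 1.28 % case fatality, versus community-treated; and an
independent 0.20 %/month pneumonia incidence with 3.33 % case fatality.
Within-cycle order is events → late detection → progression → accrual →
discounting. Fatal events still incur their treatment cost; state costs
(drug/maintenance or CB treatment) accrue to survivors; life-years accrue
1/12 per surviving patient-month; QALYs weight life-years by the state
utility (0.81 / 0.72 / 0.67) times multiplicative event-month corrections
(0.85 outpatient exacerbation, 0.50 inpatient, 0.50 pneumonia — both
corrections multiply if exacerbation and pneumonia co-occur). Costs and
effects discount at 3.5 %/year via `(1 + r)^(−cycle/12)`. No half-cycle
correction by default (negligible at monthly cycles; a mid-cycle averaging
option exists). Non-COPD patients accrue no post-tree costs or outcomes:
their CB care is identical across arms and cancels in increments — this
changes absolute, not incremental, results.

**Background mortality** is a configurable constant annual probability,
default 0, because the published inputs contain only event-specific
mortality. Consequently absolute life-years (~6.5 discounted per
screened patient) are much larger than the originally reported 2.10–2.64,
whose life-year accounting is not recoverable from the published inputs;
all conclusions are drawn from incremental comparisons, which is also how
the acceptance checks are framed.

## Economics

Discounted per-screened-patient totals per arm; pairwise comparisons
B vs A, C vs B, C vs A. ICER = ΔC/ΔQ, flagged undefined when |ΔQ| <
10⁻⁹ QALY (dominance then classified by cost sign). NMB = WTP·ΔQ − ΔC at
WTP ¥193,932/QALY. All arithmetic is full-precision 2018 CNY; the 0.1511
USD conversion is display-only (`--usd`).

## Sensitivity analyses

**One-way.** Every published input varies over its printed range: heights
and test accuracies ±10 %, hospital-exacerbation case fatality 0.5–10 %,
CB treatment cost ¥100–500, discount rates 0–5 %, everything else ±20 %
(probabilities capped at 1). Perturbing one severity-split fraction
rescales the other two proportionally to preserve the sum-to-one
constraint. The tornado reports both ICER and incremental NMB at the
default WTP; NMB is the sort key because ICER bars are ill-behaved for
dominant strategies.

**Probabilistic.** 1000 seeded draws through the full model. The printed
(low, high) bounds are read as a central 95 % interval, σ = (high −
low)/3.92: beta (method of moments, mean = base) for probabilities, test
accuracies, utilities and corrections; gamma for costs; zero-truncated
normal for treatment effects, the decline rate, heights, and age;
discount rates fixed. Severity-split draws are renormalized. The
state-utility triple is rejection-sampled to satisfy mild ≥ moderate ≥
severe: independent marginals would place the severe state above the
moderate one in roughly a quarter of draws, a logically incoherent
health-state ordering that reverses the sign of progression benefits
(disease progression cannot raise quality of life); rejection keeps the
documented marginal families while restricting draws to the coherent
region. Draw seeds derive from one master seed via a seeded integer
stream, so the whole analysis is reproducible. The CEAC marks an arm cost-effective when its
NMB is maximal among the three arms (a pairwise mode mirrors two-curve
plots).

**Scenario.** "No confirmation": the spirometer arm skips the
confirmatory test for screen positives, removing (TP + FP) × ¥220 ≈
¥72,400 per 1000 screened; everything else, including the questionnaire
arm, is unchanged.

**Treatment-duration sweep.** Implemented as a model-horizon sweep
(default 12, 60, 120, 240, 480 cycles): the longer treatment and accrual
run, the lower each comparison's ICER, from cost-effective toward
cost-saving. In the first months the QALY gain is exactly zero and the
ICER undefined, so the monotonicity property is evaluated over horizons
where the ICER is defined.

## Validation

A patient-level Monte-Carlo microsimulation implements the same rules
(identical event ordering, costs, corrections, blended regimen) and its
expectation provably equals the cohort engine's accrual formulas; the
tests require agreement within three Monte-Carlo standard errors at
n = 4000 patients for the base case, a one-way extreme, and a
probabilistic draw, and exact agreement in a fully deterministic
configuration. Mass conservation (living mass + cumulative deaths = 1)
is asserted every cycle, with an internal consistency abort on negative
mass.

## What the default configuration does and does not emulate

The default parameter set *is* the published study configuration
(Tables of test accuracy, cohort composition, clinical inputs, costs,
utilities, discounting), so passing tests show the screening logic,
FEV1-driven progression, and economics behave as that study describes.
They do not show calibration to real Chinese CB cohorts beyond those
inputs: no background mortality, no correlation between drawn parameters,
no ICS-attributable pneumonia risk, no adverse events beyond exacerbation
and pneumonia, and a cohort homogeneous in age and height within sex.

## Known limitations

* Absolute costs/life-years are not comparable to the original report
  (background-mortality accounting unrecoverable); incremental results
  carry the conclusions.
* The published upper one-way bound for the severe-state utility (0.80)
  exceeds the moderate-state utility (0.72). Because arm QALY differences
  here are carried mainly by time redistribution across severity states,
  that inversion makes delaying severe progression *reduce* QALYs: at that
  single printed bound screening is cost-saving with a QALY loss — a
  tradeoff with positive NMB — rather than strictly dominant. All other
  53 parameters preserve strict dominance at both bounds. One-way bounds
  are applied verbatim as printed, so no ordering constraint is imposed
  there (unlike in the probabilistic draws).
* Non-COPD patients accrue nothing after the tree; add their CB costs if
  absolute budget impact is needed.
* The age-spline is frozen at baseline age; the cohort does not "age
  through" the reference equation.
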