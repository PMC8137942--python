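# copdscreen

A health-economic decision model for **COPD screening among
chronic-bronchitis (CB) patients in primary care in China**: should a
primary-care practice screen CB patients for chronic obstructive pulmonary
disease with a portable spirometer, a screening questionnaire, or not at
all (usual care)?

The package is aimed at health-economics analysts and modellers. It
implements, as a tested and reusable Python library plus CLI:

* a **one-time screening decision tree** (1000 CB patients per arm; test
  sensitivity/specificity; confirmatory diagnostic spirometry for screen
  positives),
* a **monthly-cycle, lifetime Markov cohort model** of seven living health
  states (non-COPD; detected/undetected × mild/moderate/severe-very-severe
  COPD) plus death, whose severity transitions are driven by deterministic
  trough-FEV1 trajectories crossing GOLD percent-of-predicted boundaries,
* full **incremental economics** (ΔC, ΔQ, ICER, dominance, net monetary
  benefit), and
* **one-way** (tornado), **probabilistic** (1000 Monte-Carlo draws, CEAC),
  **scenario** (no confirmatory test), and **treatment-duration** sweeps.

## Model core

Predicted normal FEV1 comes from sex-specific Chinese reference equations,

```
FEV1_male   = exp(−10.61669 + 2.27078·ln(height) + 0.06622·ln(age) + Mspline)
FEV1_female = exp( −9.69716 + 2.09385·ln(height) + 0.02006·ln(age) + Mspline)
```

with the age-spline term `Mspline` calibrated so that 80 % of predicted
FEV1 at the cohort's mean height and age equals the published
mild-to-moderate boundary (1.77 L female, 2.44 L male); 50 % of predicted
gives the moderate-to-severe boundary (1.11 L / 1.52 L). Patients enter
at the midpoint of their GOLD grade (90 %, 65 %, 25 % of predicted).
Detected patients gain `ΔFEV1/month` for 6 months (treatment-mix–weighted),
then decline at 0.041 L/year ÷ 12; undetected patients decline from the
first cycle and may be diagnosed late at severity-specific annual rates
(converted via `p_month = 1 − (1 − p_year)^(1/12)`). Each cycle carries
severity-specific exacerbation risk (hospital vs community, with case
fatality for hospital-treated events), independent pneumonia risk, costs
(2018 CNY), state utilities with multiplicative event-month corrections,
and 3.5 %/year discounting of costs and effects. Economics are reported
per screened patient; strategy B is *dominant* over A when it costs less
and yields more QALYs, and `NMB = WTP·ΔQ − ΔC` at WTP = ¥193,932/QALY
(3× 2018 GDP per capita).

## Worked example

```python
from copdscreen import default_parameters, run_arms, compare_all

ps = default_parameters()               # the full published input set
res = run_arms(ps)                      # tree + 480-cycle Markov per arm
for name, r in res.items():
    print(name, round(r.total_cost), round(r.qalys, 3))
comps = compare_all(
    [res["no_screening"], res["questionnaire"], res["portable_spirometer"]],
    wtp=ps.settings.wtp,
)
```

prints (discounted, per screened patient):

```
no_screening           cost=63448  LY=6.501  QALY=4.515
questionnaire          cost=60414  LY=6.506  QALY=4.562
portable_spirometer    cost=59907  LY=6.507  QALY=4.569

questionnaire vs no_screening          dC= -3034  dQ=0.0473  ICER= -64108  dominant
portable_spirometer vs questionnaire   dC=  -507  dQ=0.0067  ICER= -75612  dominant
portable_spirometer vs no_screening    dC= -3541  dQ=0.0540  ICER= -65536  dominant
```

Reading: spirometer screening saves about ¥3,541 per screened patient and
gains 0.054 QALYs relative to usual care — it *dominates* (is cost-saving
and more effective than) both comparators, and questionnaire screening
dominates usual care, reproducing the published qualitative conclusion.
Absolute per-patient levels are larger than the original report because
the model applies only the published cause-specific mortality (no
background mortality; see `docs/methods.md`).

The same analyses from the shell:

```bash
copdscreen compare --out table.csv
copdscreen owsa --out tornado.csv
copdscreen psa --n 1000 --seed 42 --out draws.csv
copdscreen scenario no-confirmation
copdscreen sweep --horizons 12,60,120,240,480
copdscreen export-defaults params.yaml && copdscreen validate params.yaml
```

Every CSV output gets a JSON manifest sidecar (command, parameter-file
hash, seed, version) so runs are reproducible bit-for-bit.

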