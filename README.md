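# neopkpd

Developmental population pharmacokinetics–pharmacodynamics of
intravenous **meropenem in neonates and young infants**, built as a
reusable, tested pipeline for pharmacometricians working on dosing of
time-dependent antibiotics in late-onset neonatal sepsis (LOS).

Meropenem kills bacteria time-dependently, so the exposure metric that
predicts efficacy is **fT>MIC** — the fraction of the dosing interval
during which free drug stays above the pathogen's minimal inhibitory
concentration. In regions where carbapenem resistance among
*K. pneumoniae* pushes the relevant MIC to 8 mg/L, standard neonatal
regimens underdose, and regimen choice has to be re-derived from a
population model of how clearance matures. This package implements that
entire workflow.

## The model

One-compartment kinetics with zero-order infusion input and first-order
elimination, parameterized by clearance CL and volume V. Typical values
scale allometrically with current weight (CW, g) and, for CL, with a
maturation function of postnatal age (PNA, d) and gestational age
(GA, wk):

```
V_i  = θ1 · (CW/2680) · exp(η_V)
CL_i = θ2 · (CW/2680)^0.75 · (PNA/12)^θ3 · (GA/36.5)^θ4 · exp(η_CL)
y    = f · (1 + σ·ε)                      (proportional residual error)
```

with η ~ N(0, Ω) log-normal between-subject variability. The final
estimates carried by `final_model()` are θ1 = 1.63 L, θ2 = 0.503 L/h,
θ3 = 0.209, θ4 = 2.14, ω_CL = 50.8 %CV, ω_V = 17.5 %CV, σ = 28.8%.

The pipeline stages, one module each:

| module | what it does |
|---|---|
| `neopkpd.cohort` | synthetic neonatal cohorts calibrated to the study population; sparse opportunistic study simulation |
| `neopkpd.pkmodel` | closed-form infusion kinetics, covariate model, steady state |
| `neopkpd.estimation` | FOCE-I objective, fitting, empirical Bayes, forward/backward covariate selection (ΔOFV 3.84 / 6.635) |
| `neopkpd.diagnostics` | CWRES, subject bootstrap, NPDE, VPC, external MPE/MAPE |
| `neopkpd.pta` | steady-state fT>MIC and Monte Carlo probability of target attainment |
| `neopkpd.io` / `neopkpd.cli` | NONMEM-convention event tables, YAML-configured CLI |

## Worked example

Simulate a 78-neonate sparse study at the final model, refit it, and ask
whether 30 mg/kg three times daily as a 1-h infusion attains the target
in preterm neonates:

```python
import numpy as np
from neopkpd import (
    CohortSpec, PDTarget, PRETERM, Regimen, empirical_bayes,
    final_model, fit, generate_cohort, generate_dataset, simulate_pta,
)

model = final_model()
cohort = generate_cohort(CohortSpec(n_subjects=78, seed=3))
study = generate_dataset(cohort, model, seed=4)
print(f"{study.n_subjects} subjects, {study.n_observations} concentrations")

result = fit(study, init=model)
print(f"OFV {result.ofv:.1f}; theta2 = {result.estimates['theta_cl']:.3f} L/h")

ebe = empirical_bayes(study, model)
print(f"median V = {np.median(list(ebe.v_per_kg.values())):.2f} L/kg")

pta = simulate_pta(model, CohortSpec(), PRETERM, Regimen(30, 8, 1),
                   PDTarget(mic_mg_L=8.0), n_subjects=2000, seed=1)
print(f"PTA {pta.pta_percent:.1f}%")
```

which prints

```
78 subjects, 109 concentrations
OFV 668.1; theta2 = 0.558 L/h
median V = 0.61 L/kg
PTA 75.2%
```

Reading: the sparse study (109 points, ~1.4 per subject) recovers the
typical clearance within ~11% of the generating value — about the
precision such a design affords. The median weight-normalized volume,
0.60 L/kg, matches the population value. The PTA of ~73% clears the 70%
decision threshold, which is why this regimen is the recommended one for
GA ≤ 37 wk: each virtual preterm neonate gets covariates from the
cohort generator, an individual CL and V with log-normal variability,
and counts as attaining if free concentration exceeds 8 mg/L for at
least 70% of the steady-state 8-h interval.

The same stages are scriptable from a shell (`neopkpd simulate-data`,
`fit`, `select-covariates`, `bootstrap`, `npde`, `vpc`,
`validate-external`, `pta`, `grid`), each driven by a small YAML config
and a master seed; identical configs give byte-identical outputs.

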