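# vancopk

Population pharmacokinetics of intravenous vancomycin in children aged
3 months to 18 years: the covariate-structured two-compartment model, Monte
Carlo probability-of-target-attainment (PTA) simulation and dose
optimization, MAP Bayesian individual estimation for model-informed
precision dosing, desk-scale population estimation, and the standard
model-evaluation diagnostics (CWRES, pcVPC, bootstrap). It is written for
pharmacometricians and antimicrobial-stewardship researchers who want a
scriptable, tested implementation of this analysis that runs entirely on
synthetic data — the underlying clinical datasets are confidential.

## The model

Linear two-compartment kinetics with zero-order infusion input. Typical
values are referenced to a 70 kg adult and scaled per child:

```
CL  = TVCL · (WT/70)^0.75 · PMA^H/(PMA^H + TM50^H) · e^(−θ_SCR (SCR − SCR_std(age)))
V1  = TVV1 · (WT/70)        Q = TVQ · (WT/70)^0.75       V2 = TVV2 · (WT/70)
SCR_std(age) = −2.37330 − 12.91367 ln(age) + 23.93581 √age
```

with TVCL = 7.56 L/h/70 kg, θ_SCR = 0.0188 L/μmol, H = 3.4 and TM50 = 47.7
weeks (fixed), TVV1 = 85.6 L/70 kg, TVQ = 1.30 L/h/70 kg, TVV2 = 286 L/70 kg;
lognormal between-subject variability on CL (22.1% CV) and V1 (32.9%),
between-occasion variability on CL (18.7%), proportional residual error
23.3%. Exposure is scored as the area under the concentration-time curve
over 24–48 h (AUC24–48) against the therapeutic window 400–650 mg·h/L,
with MIC fixed at 1 mg/L so AUC/MIC ≡ AUC. All kinetics are closed-form
(hybrid-constant matrix exponentials, exact piecewise AUC integrals),
vectorized across subjects sharing an infusion schedule.

## Worked example

```python
import numpy as np
from vancopk import PopParams, SubjectCovariates, typical_params
from vancopk.dosing import optimize_dose, standard_dose_result
from vancopk.cohort import table3_subgroups

pop = PopParams.final_model()          # packaged parameter set

cov = SubjectCovariates(age=0.6, wt=7.8, scr=20.0)
ind = typical_params(pop, cov)
print(f"typical CL = {ind.cl:.3f} L/h, V1 = {ind.v1:.2f} L")

infant = table3_subgroups()[0]         # 3 months-1 year, SCR 10-30 umol/L
std = standard_dose_result(pop, infant, seed=1)
opt = optimize_dose(pop, infant, seed=1)
print(f"standard 15 mg/kg q6h: PTA {100*std.pta:.1f}%, "
      f"median trough {std.trough_median:.2f} mg/L")
print(f"optimized: {opt.dose:.0f} mg/kg q6h, PTA {100*opt.pta:.1f}%")
```

prints

```
typical CL = 1.224 L/h, V1 = 9.54 L
standard 15 mg/kg q6h: PTA 15.7%, median trough 9.28 mg/L
optimized: 22 mg/kg q6h, PTA 73.7%
```

— the typical infant clears about 1.2 L/h, the fixed 15 mg/kg q6h regimen
leaves most simulated infants below the 400 mg·h/L efficacy floor, and the
escalation rule (lowest dose reaching 95% of the best grid PTA, common
random numbers across the grid) raises the dose to 22 mg/kg, raising
target attainment more than fourfold. A command-line interface exposes the same pipeline
(`vancopk pta`, `optimize-dose`, `loading-dose`, `map-dose`, `fit`,
`bootstrap`, `vpc`); every run writes a JSON log of its resolved
configuration and seed.

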