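# Methods

## Model

Vancomycin disposition in children (3 months to 18 years) is described by a
linear two-compartment model with zero-order infusion input and first-order
elimination. Typical parameters are referenced to a 70 kg adult and scaled
to each child:

    CL  = TVCL * (WT/70)^0.75 * F_mat(PMA) * F_renal(SCR, age)
    V1  = TVV1 * (WT/70)
    Q   = TVQ  * (WT/70)^0.75
    V2  = TVV2 * (WT/70)

* **Allometry.** Clearances scale with weight to the 0.75 power, volumes
  linearly — the standard theory-based scaling for pediatric PK.
* **Maturation.** `F_mat = PMA^H / (PMA^H + TM50^H)` with the Hill
  coefficient H = 3.4 and TM50 = 47.7 weeks held fixed (they cannot be
  estimated from data that start at 3 months postnatal age). At a
  postmenstrual age of 2 years the function reaches 93.5% of its asymptote.
  An optional postnatal-age transition factor
  `1 - PNA_max * exp(-ln2 * PNA/PNA_T50)` can multiply `F_mat`; the shipped
  final model carries no values for its two parameters, so the operation is
  available but inert by default.
* **Renal function.** `F_renal = exp(-theta_SCR * (SCR - SCR_std(age)))`
  where `SCR_std(age) = -2.37330 - 12.91367 ln(age) + 23.93581 sqrt(age)`
  (umol/L) is a pediatric age-standardized creatinine reference. The
  function is not monotone in age: it has an interior minimum near 1.2
  years, and only increases beyond roughly age 2. The intercept sign is
  printed inconsistently in secondary sources; we use the negative
  intercept, which reproduces the reference value 21.56251 umol/L at age 1
  and plausible values across childhood, and expose all three coefficients
  as parameters.

Random effects are lognormal: between-subject deviations on CL
(omega = 0.221) and V1 (0.329), and a between-occasion deviation on CL
(0.187) redrawn per treatment occasion (a new occasion starts when
consecutive doses are more than 24 h apart). Residual error is proportional,
DV = f(1 + 0.233 eps). The packaged default parameter set is
`src/vancopk/data/table2_final.json`.

## Kinetics

Concentrations and AUCs are computed in closed form, not by numerical
integration. Between consecutive infusion start/stop boundaries the input
rate is constant, and the two-compartment state propagates by the analytic
matrix exponential written in terms of the hybrid rate constants alpha and
beta; the running integral of the central amount is propagated by the same
expansion, so any AUC window is exact up to floating point. Numerical
choices:

* the discriminant of the characteristic polynomial is expanded in the
  cancellation-free form `(k10-k21)^2 + k12 (k12 + 2 k10 + 2 k21)`;
* beta is computed as `k10 k21 / alpha` (stable for small roots);
* when `(alpha-beta)/alpha < 1e-9` the repeated-root series
  `exp(Mt) = e^{-alpha t}(I + (M + alpha I) t)` replaces the two-exponential
  form;
* the solver is vectorized over all subjects sharing one infusion schedule,
  which is what makes 9 x 26 x 1000 subject-regimen simulations take
  seconds.

The unit tests pin the solver against a stiff-tolerance ODE integration on
100 randomized regimens (relative error < 1e-6) and against the mass-balance
identities AUC(0, inf) = dose/CL and steady-state interval AUC = dose/CL.

## Virtual cohorts and synthetic TDM data

The clinical datasets behind the model are confidential, so every analysis
here runs on declared synthetic stand-ins:

* **Subgroup cohorts** (dosing simulations): age and serum creatinine
  uniform within each of the nine published age/SCR bands; weight is a
  packaged smooth unisex median weight-for-age curve (PCHIP through
  growth-reference anchor medians; 22.4 kg at age 6.8 years, matching the
  development cohort's median weight of 22.9 kg) times a lognormal(0, 0.15)
  deviation; PMA is derived from age assuming term gestation
  (PMA = 52.1775 age + 40).
* **Reference cohorts** (estimation and diagnostics): age log-uniform on
  [0.25, 18] years (young children oversampled, as in pediatric TDM
  datasets); SCR lognormal around the age-standard value with log-SD 0.55,
  chosen so the simulated spread covers the published development-cohort
  range (median 31, range 10–328 umol/L); weight as above.
* **TDM sampling**: 1–6 samples per subject with median 3, trough-weighted
  (60% of samples in the hour before a dose); observations below a 2 mg/L
  quantification limit are dropped and counted. The generating random
  effects are recorded for recovery tests.

What these stand-ins do **not** emulate: the joint skew of the real
covariate database within each band (real SCR within a band concentrates at
the healthy end), preterm-born children (PMA below the term line), ICU
fluid-status effects on V1, or assay-specific error structure. Simulation
results therefore match the published dosing table within the stated
stochastic tolerances (about +/-10 percentage points of PTA) rather than to
the digit, and agreement on synthetic data says nothing new about fit to the
confidential clinical data.

## Dosing simulations

Each subgroup gets 1,000 virtual subjects. Regimens are 1-h infusions every
6 h over a 48-h horizon; per-dose amounts are mg/kg times simulated weight,
rounded to 1 mg. The efficacy index is the AUC over 24–48 h against the
closed window [400, 650] mg·h/L (MIC fixed at 1 mg/L, so AUC/MIC = AUC);
exposures above 650 are flagged supratherapeutic. Troughs are the model
concentrations immediately before the 24-h and 48-h doses. Residual error is
not added to simulated exposures (AUC is a state quantity).

Virtual dosing cohorts carry between-subject variability only. A simulated
initial course is a single treatment occasion, and applying the
between-occasion deviation on top of the between-subject one would widen
the simulated clearance log-spread to at least 0.29, which caps the
best-case window probability near 75% — below subgroup target-attainment
values the dosing table actually reaches (up to 80%). Occasion-level
variability therefore stays in the model for estimation, individual
forecasting and synthetic TDM generation, but is not drawn for virtual
dosing cohorts (a flag restores it).

The escalation optimizer evaluates PTA on a 5–30 mg/kg grid (1 mg/kg steps)
under common random numbers — the cohort and all random effects are drawn
once per subgroup and reused across grid doses and arms — and selects the
lowest dose whose PTA is at least 95% of the grid maximum. "Overall PTA" is
the unweighted mean over the nine subgroups. The loading-dose arm replaces
the first maintenance dose with a 25 mg/kg 1-h infusion and is scored on the
0–24 h window. Daily-dose caps are available but off by default.

## Individual (MAP) estimation

With population parameters fixed, a subject's random-effect modes minimize

    sum_j [ (DV_j - f_j)^2/(sigma^2 f_j^2) + ln(sigma^2 f_j^2) ]
        + eta' Omega^-1 eta + sum_occ kappa_occ^2/omega_IOV^2

(the interaction term is retained inside the objective). The optimizer is a
damped Newton iteration with finite-difference derivatives on the <= 4
active random-effect dimensions, vectorized across subjects sharing a
schedule, with multistart from 0 and +/-1 prior SD and a Nelder-Mead polish
for single subjects; convergence tolerance 1e-8 on the objective.
Zero-variance dimensions are dropped from the search. Whether the
between-occasion deviations are estimated is a flag (default: estimated for
observed occasions). The dose proposal puts the predicted steady-state daily
AUC at the window midpoint: daily dose = 525 x CL, ignoring future-occasion
variability (whose conditional expectation is the subject-level mode).

## Population estimation

The marginal likelihood is approximated by the Laplace method at each
subject's conditional mode with the interaction term retained (the
first-order-conditional-with-interaction family at desk scale). Per subject,

    OFV_i = h(eta_hat) + ln|Omega| + ln det(0.5 d2h/deta2)

with the additive n_obs ln(2pi) constant omitted; at Omega -> 0 this
collapses exactly to the residual -2LL of the typical model. The outer
optimizer is Nelder-Mead over log-transformed parameters with a warm-started
cache of conditional modes. The maturation shape (Hill, TM50) is always
fixed; recovery experiments additionally fix TVQ, TVV2 and the IOV SD, which
a sparse single-occasion q6h design cannot inform. A per-subject
nonparametric bootstrap (resample subjects with replacement, refit, report
median and 2.5/97.5 percentiles, count non-converged replicates) mirrors the
usual robustness table.

Desk-scale problem sizes: the recovery experiment uses 200 subjects with
four samples each at informative times (1.05, 3.5, 23.9, 47.9 h — an
end-of-infusion peak, a mid-interval point and two troughs) and no LLOQ
censoring, since the estimator does not model censoring; this recovers TVCL,
TVV1 and theta_SCR within 10%. Bootstrap examples run tens of replicates on
tens of subjects.

## Diagnostics

* **CWRES**: the model is linearized at the conditional mode;
  `E[DV] = f(eta_hat) - F eta_hat`, `Cov = F Omega F' + diag(sigma^2
  f(eta_hat)^2)`, and residuals are whitened by the Cholesky factor of Cov
  (ridge 1e-10 on singular covariances, with a warning). On model-true data
  the empirical mean is within +/-0.1 and the variance within [0.8, 1.2].
* **pcVPC**: observations (and every simulated replicate, 1,000 by default)
  are scaled by bin-median population prediction over subject-specific
  population prediction; binning is by time after the previous dose with
  quantile-based edges (configurable), bins with fewer than five
  observations merge leftward; the observed 5th/50th/95th percentiles are
  compared with 95% confidence bands of the same percentiles across
  replicates. Stratification by infusion mode (intermittent vs continuous)
  is the only stratification implemented.

## Scope and limitations

Time-varying covariates (changing SCR under therapy), saturable
elimination, ECMO/dialysis populations, covariate model search, and
parameter-uncertainty propagation into the simulations are out of scope.
The published parameter estimates themselves are reproduced as a packaged
constant set, not re-estimated — the source datasets are confidential — and
all estimation claims in this package are statements about synthetic-data
recovery.
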