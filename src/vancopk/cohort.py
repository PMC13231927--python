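"""Synthetic pediatric cohorts and therapeutic-drug-monitoring datasets.

Two generators live here:

* :func:`sample_cohort` draws virtual covariate cohorts for the dosing
  simulations — age and serum creatinine uniform within a subgroup band,
  weight from a packaged smooth median weight-for-age curve times a
  lognormal deviation.
* :func:`synthesize_tdm` turns a cohort into a full sparse-sampling TDM
  dataset (doses, observation times, proportional residual error) with the
  generating random effects recorded for recovery tests.

The real multi-center covariate database behind the published simulations is
confidential, so the uniform-band/lognormal-weight construction is this
package's declared stand-in; every distribution is overridable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from io import StringIO
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .dataio import TdmDataset
from .popmodel import (
    PopParams,
    Regimen,
    RegimenSolution,
    SubjectCovariates,
    typical_params,
)

__all__ = [
    "SubgroupSpec",
    "table3_subgroups",
    "median_weight",
    "sample_cohort",
    "sample_reference_cohort",
    "synthesize_tdm",
    "default_regimen_policy",
    "OCCASION_GAP_H",
    "DEFAULT_LLOQ",
]

#: a new treatment occasion begins when consecutive doses are more than
#: this many hours apart
OCCASION_GAP_H = 24.0

#: lower limit of quantification, mg/L; observations below it are dropped
DEFAULT_LLOQ = 2.0

WT_LOG_SD = 0.15


@dataclass(frozen=True)
class SubgroupSpec:
    """One simulated subgroup: an age band (years) and a SCR band (umol/L)."""

    label: str
    age_band: tuple[float, float]
    scr_band: tuple[float, float]
    n: int = 1000

    def __post_init__(self) -> None:
        if not (0 < self.age_band[0] < self.age_band[1]):
            raise ValueError(f"invalid age band {self.age_band}")
        if not (0 < self.scr_band[0] < self.scr_band[1]):
            raise ValueError(f"invalid SCR band {self.scr_band}")
        if self.n < 0:
            raise ValueError("n must be >= 0")


def table3_subgroups() -> tuple[SubgroupSpec, ...]:
    """The nine age/creatinine subgroups of the published dosing table."""
    text = resources.files("vancopk.data").joinpath("table3_subgroups.json").read_text()
    return tuple(
        SubgroupSpec(
            label=d["label"],
            age_band=tuple(d["age_band"]),
            scr_band=tuple(d["scr_band"]),
            n=d["n"],
        )
        for d in json.loads(text)
    )


def _weight_curve() -> PchipInterpolator:
    text = resources.files("vancopk.data").joinpath("weight_for_age.csv").read_text()
    tbl = pd.read_csv(StringIO(text))
    return PchipInterpolator(tbl["age_years"], tbl["median_weight_kg"], extrapolate=True)


_CURVE: PchipInterpolator | None = None


def median_weight(age):
    """Smooth unisex median weight-for-age (kg), monotone in age."""
    global _CURVE
    if _CURVE is None:
        _CURVE = _weight_curve()
    age = np.clip(np.asarray(age, dtype=float), 0.0, 18.0)
    out = _CURVE(age)
    return float(out) if out.ndim == 0 else out


def sample_cohort(spec: SubgroupSpec, seed, wt_log_sd: float = WT_LOG_SD
                  ) -> list[SubjectCovariates]:
    """Draw a virtual covariate cohort for one subgroup.

    Age ~ U(age band), SCR ~ U(scr band), weight = median-for-age times a
    lognormal(0, ``wt_log_sd``) deviation; PMA derived from age assuming
    term gestation.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    age = rng.uniform(*spec.age_band, size=spec.n)
    scr = rng.uniform(*spec.scr_band, size=spec.n)
    wt = median_weight(age) * np.exp(rng.normal(0.0, wt_log_sd, size=spec.n))
    return [
        SubjectCovariates(age=a, wt=w, scr=s)
        for a, w, s in zip(age, wt, scr)
    ]


def sample_reference_cohort(n: int, seed, age_range=(0.25, 18.0),
                            scr_log_sd: float = 0.55,
                            wt_log_sd: float = WT_LOG_SD
                            ) -> list[SubjectCovariates]:
    """Covariate cohort shaped like a general hospital TDM population.

    Ages log-uniform over ``age_range`` (young children oversampled, as in
    pediatric TDM datasets); SCR lognormal around the age-standard value;
    weight from the median curve.  Used for estimation/diagnostic testing
    where wide covariate spread is needed.
    """
    from .popmodel import scr_std

    rng = np.random.default_rng(seed)
    age = np.exp(rng.uniform(np.log(age_range[0]), np.log(age_range[1]), size=n))
    scr = scr_std(age) * np.exp(rng.normal(0.0, scr_log_sd, size=n))
    scr = np.maximum(scr, 5.0)
    wt = median_weight(age) * np.exp(rng.normal(0.0, wt_log_sd, size=n))
    return [SubjectCovariates(age=a, wt=w, scr=s) for a, w, s in zip(age, wt, scr)]


# ---------------------------------------------------------------------------
# Synthetic TDM datasets
# ---------------------------------------------------------------------------

def assign_occasions(dose_times, gap_h: float = OCCASION_GAP_H) -> np.ndarray:
    """Occasion index per dose: a new treatment occasion starts whenever the
    gap since the previous dose exceeds ``gap_h`` hours."""
    t = np.asarray(dose_times, dtype=float)
    if len(t) == 0:
        return np.zeros(0, dtype=int)
    if np.any(np.diff(t) < 0):
        raise ValueError("dose times must be non-decreasing")
    return np.concatenate([[0], np.cumsum(np.diff(t) > gap_h)]).astype(int)


def default_regimen_policy(cov: SubjectCovariates,
                           dose_per_kg: float = 15.0,
                           n_doses: int = 8) -> Regimen:
    """Standard empirical dosing: 15 mg/kg 1-h infusions q6h (rounded to 1 mg)."""
    return Regimen.intermittent(round(dose_per_kg * cov.wt), n_doses=n_doses)


def two_occasion_policy(cov: SubjectCovariates,
                        dose_per_kg: float = 15.0) -> Regimen:
    """Two q6h treatment episodes separated by a 72-h gap; the gap rule
    makes the second episode a new occasion."""
    from .popmodel import InfusionEvent

    times = np.concatenate([np.arange(0.0, 48.0, 6.0),
                            np.arange(120.0, 168.0, 6.0)])
    occs = assign_occasions(times)
    dose = round(dose_per_kg * cov.wt)
    events = tuple(InfusionEvent(t, dose, 1.0, int(o))
                   for t, o in zip(times, occs))
    return Regimen(events, horizon=168.0)


def _default_sampling(rng: np.random.Generator, reg: Regimen) -> np.ndarray:
    """Sparse trough-weighted sampling: 1-6 samples/subject, median 3."""
    n_samples = rng.choice([1, 2, 3, 4, 5, 6], p=[0.1, 0.2, 0.3, 0.2, 0.1, 0.1])
    starts = np.array(reg.start_times)
    times = []
    for _ in range(n_samples):
        i = rng.integers(1, len(starts))  # interval ending at dose i
        if rng.random() < 0.6:            # pre-dose trough window
            t = starts[i] - rng.uniform(0.0, 1.0)
        else:
            t = rng.uniform(starts[i - 1] + 0.25, starts[i])
        times.append(t)
    return np.sort(np.array(times))


def synthesize_tdm(
    pop: PopParams,
    cohort: Sequence[SubjectCovariates],
    regimen_policy: Callable[[SubjectCovariates], Regimen] | None = None,
    sampling_policy: Callable[[np.random.Generator, Regimen], np.ndarray] | None = None,
    seed=0,
    lloq: float = DEFAULT_LLOQ,
) -> TdmDataset:
    """Simulate a sparse TDM dataset from a covariate cohort.

    For each subject, between-subject effects (eta on CL and V1) and one
    between-occasion effect per regimen occasion are drawn lognormally,
    concentrations are evaluated at the sampled times, and proportional
    residual error is applied: DV = f * (1 + sigma_prop * eps).  Records
    below ``lloq`` (or before the first dose) are dropped and counted.
    The generating truth is kept on the returned dataset.
    """
    regimen_policy = regimen_policy or default_regimen_policy
    sampling_policy = sampling_policy or _default_sampling
    rng = np.random.default_rng(seed)

    rows, truth_rows = [], []
    n_dropped = 0
    for sid, cov in enumerate(cohort, start=1):
        reg = regimen_policy(cov)
        n_occ = reg.n_occasions
        typ = typical_params(pop, cov)
        eta_cl = rng.normal(0.0, pop.omega_cl)
        eta_v1 = rng.normal(0.0, pop.omega_v1)
        kappa = rng.normal(0.0, pop.omega_iov_cl, size=n_occ)
        cl = typ.cl * np.exp(eta_cl)
        v1 = typ.v1 * np.exp(eta_v1)

        t_obs = np.asarray(sampling_policy(rng, reg), dtype=float)
        first_dose = reg.events[0].start
        keep = t_obs >= first_dose
        n_dropped += int((~keep).sum())
        t_obs = t_obs[keep]

        sol = RegimenSolution(
            cl, v1, typ.q, typ.v2,
            np.array([e.start for e in reg.events]),
            np.array([e.duration for e in reg.events]),
            np.array([e.occ for e in reg.events], dtype=int),
            np.array([e.dose for e in reg.events]),
            reg.horizon,
            kappa=kappa[None, :],
        )
        f = np.atleast_1d(sol.conc(t_obs)) if len(t_obs) else np.array([])
        eps = rng.normal(0.0, 1.0, size=len(t_obs))
        dv = f * (1.0 + pop.sigma_prop * eps)
        ok = dv >= lloq
        n_dropped += int((~ok).sum())

        starts = np.array([e.start for e in reg.events])
        occs = np.array([e.occ for e in reg.events], dtype=int)
        for e in reg.events:
            rows.append(dict(ID=sid, TIME=e.start, AMT=e.dose, DUR=e.duration,
                             DV=np.nan, EVID=1, MDV=1, OCC=e.occ,
                             AGE=cov.age, WT=cov.wt, SCR=cov.scr, PMA=cov.pma))
        for t, y in zip(t_obs[ok], dv[ok]):
            occ = int(occs[np.searchsorted(starts, t, side="right") - 1])
            rows.append(dict(ID=sid, TIME=t, AMT=np.nan, DUR=np.nan,
                             DV=y, EVID=0, MDV=0, OCC=occ,
                             AGE=cov.age, WT=cov.wt, SCR=cov.scr, PMA=cov.pma))
        truth_rows.append(dict(
            ID=sid, eta_cl=eta_cl, eta_v1=eta_v1,
            **{f"kappa_{o}": kappa[o] for o in range(n_occ)},
            cl=cl, v1=v1, q=typ.q, v2=typ.v2,
        ))

    df = pd.DataFrame(rows).sort_values(["ID", "TIME", "EVID"],
                                        kind="stable").reset_index(drop=True)
    return TdmDataset(df=df, truth=pd.DataFrame(truth_rows),
                      n_dropped_lloq=n_dropped)
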