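"""Structural and covariate model for vancomycin disposition in children.

The drug follows linear two-compartment kinetics with zero-order (infusion)
input into the central compartment.  Clearance is built multiplicatively from
a typical value referenced to a 70 kg adult:

    CL = TVCL * (WT/70)**0.75 * F_mat(PMA) * F_renal(SCR, age)

where ``F_mat`` is a sigmoid (Hill) maturation function of postmenstrual age
and ``F_renal`` is an exponential effect of the deviation of serum creatinine
from an age-standardized reference.  Volumes scale linearly with weight and
intercompartmental clearance allometrically (exponent 0.75).

All kinetics are evaluated in closed form via the hybrid rate constants
(alpha, beta); concentrations and AUC windows are exact piecewise-analytic
quantities, not quadrature.  The solver is vectorized over subjects that
share one infusion schedule, which is what makes the Monte Carlo dosing
simulations cheap.

Units throughout: time h, dose mg, volume L, concentration mg/L,
creatinine umol/L, weight kg, PMA weeks, age years, PNA days.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np

__all__ = [
    "PopParams",
    "SubjectCovariates",
    "IndividualParams",
    "InfusionEvent",
    "Regimen",
    "scr_std",
    "f_size",
    "f_mat",
    "f_mat_pna",
    "f_renal",
    "typical_params",
    "concentration",
    "auc",
    "trough",
    "RegimenSolution",
    "solve_regimen",
]

WEEKS_PER_YEAR = 52.1775
TERM_GESTATION_WEEKS = 40.0

# Age-standardized serum creatinine reference (pediatric), umol/L:
# scr_std(age) = a + b*ln(age) + c*sqrt(age).  The intercept sign follows the
# primary pediatric reference formula; it is exposed for sensitivity analyses.
SCR_STD_INTERCEPT = -2.37330
SCR_STD_LOG_COEF = -12.91367
SCR_STD_SQRT_COEF = 23.93581

_HYBRID_DEGENERACY_TOL = 1e-9


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopParams:
    """Population fixed effects, variance components and residual error.

    Defaults are the final published estimates for the pediatric model this
    package implements (clearances in L/h per 70 kg, volumes in L per 70 kg,
    random-effect magnitudes as SDs on the log scale, residual error as a
    proportional SD).
    """

    tvcl: float = 7.56
    tvv1: float = 85.6
    tvq: float = 1.30
    tvv2: float = 286.0
    hill: float = 3.4
    tm50: float = 47.7
    theta_scr: float = 0.0188
    omega_cl: float = 0.221
    omega_v1: float = 0.329
    omega_iov_cl: float = 0.187
    sigma_prop: float = 0.233
    pna_max: float | None = None
    pna_t50: float | None = None

    def __post_init__(self) -> None:
        for name in ("tvcl", "tvv1", "tvq", "tvv2", "hill", "tm50", "theta_scr"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        for name in ("omega_cl", "omega_v1", "omega_iov_cl", "sigma_prop"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.pna_max is not None and not (0.0 <= self.pna_max <= 1.0):
            raise ValueError(f"pna_max must lie in [0, 1], got {self.pna_max!r}")
        if self.pna_t50 is not None and self.pna_t50 <= 0:
            raise ValueError(f"pna_t50 must be > 0, got {self.pna_t50!r}")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        return {k: v for k, v in d.items() if v is not None}

    @classmethod
    def from_dict(cls, d: dict) -> "PopParams":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown PopParams fields: {sorted(unknown)}")
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "PopParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def final_model(cls) -> "PopParams":
        """Packaged final parameter set (``data/table2_final.json``)."""
        text = resources.files("vancopk.data").joinpath("table2_final.json").read_text()
        return cls.from_dict(json.loads(text))

    def replace(self, **kw) -> "PopParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class SubjectCovariates:
    """Covariates for one subject at one occasion.

    ``pma`` defaults to term gestation (40 weeks) plus postnatal age; pass it
    explicitly for preterm-born subjects.  The implied gestational age must
    fall in ``ga_window`` weeks.
    """

    age: float          # years
    wt: float           # kg
    scr: float          # umol/L
    pma: float | None = None   # weeks
    pna: float | None = None   # days
    ga_window: tuple[float, float] = (22.0, 45.0)

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError(f"age must be > 0, got {self.age!r}")
        if self.wt <= 0:
            raise ValueError(f"wt must be > 0, got {self.wt!r}")
        if self.scr <= 0:
            raise ValueError(f"scr must be > 0, got {self.scr!r}")
        if self.pma is None:
            object.__setattr__(
                self, "pma", self.age * WEEKS_PER_YEAR + TERM_GESTATION_WEEKS
            )
        if self.pma < 22.0:
            raise ValueError(f"pma must be >= 22 weeks, got {self.pma!r}")
        ga = self.pma - self.age * WEEKS_PER_YEAR
        lo, hi = self.ga_window
        if not (lo <= ga <= hi):
            raise ValueError(
                f"pma {self.pma:.1f} wk inconsistent with age {self.age:.2f} y "
                f"(implied gestational age {ga:.1f} wk outside [{lo}, {hi}])"
            )
        if self.pna is not None and self.pna < 0:
            raise ValueError(f"pna must be >= 0, got {self.pna!r}")


@dataclass(frozen=True)
class IndividualParams:
    """Realized individual parameters.

    ``kappa_cl`` holds one between-occasion deviation per occasion index;
    the effective clearance during occasion *o* is ``cl * exp(kappa_cl[o])``
    (``cl`` already carries the between-subject deviation ``eta_cl``).
    """

    cl: float
    v1: float
    q: float
    v2: float
    eta_cl: float = 0.0
    eta_v1: float = 0.0
    kappa_cl: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        for name in ("cl", "v1", "q", "v2"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")

    @property
    def k10(self) -> float:
        return self.cl / self.v1

    @property
    def k12(self) -> float:
        return self.q / self.v1

    @property
    def k21(self) -> float:
        return self.q / self.v2

    @property
    def hybrid_constants(self) -> tuple[float, float]:
        """(alpha, beta) with alpha > beta > 0.

        The discriminant is expanded as (k10-k21)^2 + k12(k12+2k10+2k21),
        which avoids the catastrophic cancellation of s^2 - 4 k10 k21 when
        the roots nearly collide.
        """
        s = self.k10 + self.k12 + self.k21
        disc = math.sqrt((self.k10 - self.k21) ** 2
                         + self.k12 * (self.k12 + 2 * self.k10 + 2 * self.k21))
        alpha = 0.5 * (s + disc)
        beta = self.k10 * self.k21 / alpha
        return alpha, beta

    def cl_at_occasion(self, occ: int) -> float:
        if occ < len(self.kappa_cl):
            return self.cl * math.exp(self.kappa_cl[occ])
        return self.cl


@dataclass(frozen=True)
class InfusionEvent:
    start: float        # h
    dose: float         # mg
    duration: float     # h
    occ: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"infusion duration must be > 0, got {self.duration!r}")
        if self.dose < 0:
            raise ValueError(f"dose must be >= 0, got {self.dose!r}")
        if self.start < 0:
            raise ValueError(f"event start must be >= 0, got {self.start!r}")

    @property
    def rate(self) -> float:
        return self.dose / self.duration


@dataclass(frozen=True)
class Regimen:
    """Ordered infusion events plus a simulation horizon."""

    events: tuple[InfusionEvent, ...]
    horizon: float

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ValueError("horizon must be > 0")
        events = tuple(self.events)
        object.__setattr__(self, "events", events)
        for a, b in zip(events, events[1:]):
            if b.start < a.start:
                raise ValueError("event times must be non-decreasing")
            if b.occ < a.occ:
                raise ValueError("occasion indices must be non-decreasing")

    @property
    def start_times(self) -> tuple[float, ...]:
        return tuple(e.start for e in self.events)

    @property
    def n_occasions(self) -> int:
        return (max((e.occ for e in self.events), default=-1)) + 1

    @classmethod
    def intermittent(
        cls,
        dose: float,
        interval: float = 6.0,
        n_doses: int = 8,
        duration: float = 1.0,
        start: float = 0.0,
        horizon: float | None = None,
        occ: int = 0,
    ) -> "Regimen":
        """Repeated short infusions, e.g. the default 1-h q6h schedule."""
        events = tuple(
            InfusionEvent(start + i * interval, dose, duration, occ)
            for i in range(n_doses)
        )
        if horizon is None:
            horizon = start + n_doses * interval
        return cls(events, horizon)

    @classmethod
    def continuous(cls, total_dose: float, duration: float,
                   start: float = 0.0, horizon: float | None = None,
                   occ: int = 0) -> "Regimen":
        if horizon is None:
            horizon = start + duration
        return cls((InfusionEvent(start, total_dose, duration, occ),), horizon)

    def scaled(self, factor: float) -> "Regimen":
        events = tuple(
            InfusionEvent(e.start, e.dose * factor, e.duration, e.occ)
            for e in self.events
        )
        return Regimen(events, self.horizon)


# ---------------------------------------------------------------------------
# Covariate model
# ---------------------------------------------------------------------------

def scr_std(
    age,
    intercept: float = SCR_STD_INTERCEPT,
    log_coef: float = SCR_STD_LOG_COEF,
    sqrt_coef: float = SCR_STD_SQRT_COEF,
):
    """Age-standardized serum creatinine reference value (umol/L)."""
    age = np.asarray(age, dtype=float)
    if np.any(age <= 0):
        raise ValueError("age must be > 0")
    out = intercept + log_coef * np.log(age) + sqrt_coef * np.sqrt(age)
    return float(out) if out.ndim == 0 else out


def f_size(wt):
    """Allometric size factor (WT/70)^0.75, dimensionless."""
    wt = np.asarray(wt, dtype=float)
    if np.any(wt <= 0):
        raise ValueError("wt must be > 0")
    out = (wt / 70.0) ** 0.75
    return float(out) if out.ndim == 0 else out


def f_mat(pma, hill: float = 3.4, tm50: float = 47.7):
    """Sigmoid maturation of clearance with postmenstrual age, in (0, 1)."""
    pma = np.asarray(pma, dtype=float)
    if np.any(pma <= 0):
        raise ValueError("pma must be > 0")
    # computed on the log scale to stay stable at large PMA
    r = (tm50 / pma) ** hill
    out = 1.0 / (1.0 + r)
    return float(out) if out.ndim == 0 else out


def f_mat_pna(pna, pna_max: float | None, pna_t50: float | None):
    """Postnatal-age transition factor: 1 - pna_max * exp(-ln2 * pna/pna_t50).

    This optional first-weeks-of-life adjustment multiplies ``f_mat``; the
    final model ships without values for its two parameters, so callers must
    supply them explicitly.
    """
    if pna_max is None or pna_t50 is None:
        raise ValueError(
            "f_mat_pna requires pna_max and pna_t50; the final model does not "
            "define them"
        )
    if not 0.0 <= pna_max <= 1.0:
        raise ValueError("pna_max must lie in [0, 1]")
    if pna_t50 <= 0:
        raise ValueError("pna_t50 must be > 0")
    pna = np.asarray(pna, dtype=float)
    if np.any(pna < 0):
        raise ValueError("pna must be >= 0")
    out = 1.0 - pna_max * np.exp(-math.log(2.0) * pna / pna_t50)
    return float(out) if out.ndim == 0 else out


def f_renal(scr, age, theta_scr: float = 0.0188, **scr_std_kw):
    """Renal covariate factor exp(-theta * (SCR - SCR_std(age))), > 0."""
    scr = np.asarray(scr, dtype=float)
    if np.any(scr <= 0):
        raise ValueError("scr must be > 0")
    out = np.exp(-theta_scr * (scr - scr_std(age, **scr_std_kw)))
    return float(out) if out.ndim == 0 else out


def typical_params(pop: PopParams, cov: SubjectCovariates) -> IndividualParams:
    """Individual parameters at zero random effects for given covariates.

    If the population parameter set carries the optional postnatal-age
    transition (``pna_max``/``pna_t50``) and the subject has a recorded PNA,
    the maturation factor is multiplied by ``f_mat_pna``.
    """
    fm = f_mat(cov.pma, pop.hill, pop.tm50)
    if pop.pna_max is not None and pop.pna_t50 is not None and cov.pna is not None:
        fm = fm * f_mat_pna(cov.pna, pop.pna_max, pop.pna_t50)
    size = f_size(cov.wt)
    cl = pop.tvcl * size * fm * f_renal(cov.scr, cov.age, pop.theta_scr)
    wfrac = cov.wt / 70.0
    return IndividualParams(
        cl=cl,
        v1=pop.tvv1 * wfrac,
        q=pop.tvq * size,
        v2=pop.tvv2 * wfrac,
    )


# ---------------------------------------------------------------------------
# Closed-form two-compartment kinetics (batched over subjects)
# ---------------------------------------------------------------------------

class RegimenSolution:
    """Piecewise-analytic solution for n subjects sharing one schedule.

    Parameters
    ----------
    cl, v1, q, v2 : array_like, shape (n,)
        Individual disposition parameters (``cl`` includes the
        between-subject deviation but not the between-occasion one).
    starts, durations, occs : array_like, shape (m,)
        Shared infusion schedule (start time h, duration h, occasion index).
    doses : array_like, shape (n, m) or (m,)
        Dose per subject and event, mg.
    horizon : float
        End of the simulated time span, h.
    kappa : array_like, shape (n, K), optional
        Between-occasion log-scale deviations of clearance; column ``o``
        applies while occasion ``o`` is the most recent dosing occasion.

    The state (amounts in both compartments) and the running integral of the
    central amount are propagated exactly across the breakpoints formed by
    every infusion start/stop; queries at arbitrary times reuse the stored
    segment states, so concentrations and AUC windows are exact up to
    floating point.
    """

    def __init__(self, cl, v1, q, v2, starts, durations, occs, doses,
                 horizon, kappa=None):
        cl = np.atleast_1d(np.asarray(cl, dtype=float))
        v1 = np.atleast_1d(np.asarray(v1, dtype=float))
        q = np.atleast_1d(np.asarray(q, dtype=float))
        v2 = np.atleast_1d(np.asarray(v2, dtype=float))
        n = len(cl)
        if min(cl.min(initial=np.inf), v1.min(initial=np.inf),
               q.min(initial=np.inf), v2.min(initial=np.inf)) <= 0:
            raise ValueError("cl, v1, q, v2 must all be > 0")
        starts = np.asarray(starts, dtype=float)
        durations = np.asarray(durations, dtype=float)
        occs = np.asarray(occs, dtype=int)
        m = len(starts)
        doses = np.asarray(doses, dtype=float)
        if doses.ndim == 1:
            doses = np.broadcast_to(doses, (n, m)).copy()
        if doses.shape != (n, m):
            raise ValueError(f"doses must have shape ({n}, {m})")
        self.n, self.v1, self.q, self.v2 = n, v1, q, v2
        self.horizon = float(horizon)

        edges = np.concatenate(([0.0, self.horizon], starts, starts + durations))
        edges = np.unique(edges[(edges >= 0.0) & (edges <= self.horizon)])
        self.edges = edges
        S = len(edges) - 1

        rates = doses / durations                      # (n, m)
        mids = 0.5 * (edges[:-1] + edges[1:])          # (S,)
        if m:
            active = (starts[None, :] <= mids[:, None]) & (
                mids[:, None] < (starts + durations)[None, :]
            )                                          # (S, m)
            self._R = rates @ active.T.astype(float)   # (n, S) mg/h
            # occasion in force during each segment = occ of latest started event
            idx = np.searchsorted(starts, mids, side="right") - 1
            seg_occ = np.where(idx >= 0, occs[np.clip(idx, 0, None)], 0)
        else:
            self._R = np.zeros((n, S))
            seg_occ = np.zeros(S, dtype=int)
        self.seg_occ = seg_occ

        if kappa is not None:
            kappa = np.atleast_2d(np.asarray(kappa, dtype=float))
            cl_eff = cl[:, None] * np.exp(kappa[:, seg_occ])   # (n, S)
        else:
            cl_eff = np.broadcast_to(cl[:, None], (n, S))
        self._k10 = cl_eff / v1[:, None]                        # (n, S)
        self._k12 = np.broadcast_to((q / v1)[:, None], (n, S))
        self._k21 = np.broadcast_to((q / v2)[:, None], (n, S))
        s = self._k10 + self._k12 + self._k21
        # cancellation-free discriminant (exact when the roots nearly collide)
        disc = np.sqrt((self._k10 - self._k21) ** 2
                       + self._k12 * (self._k12 + 2 * self._k10 + 2 * self._k21))
        self._alpha = 0.5 * (s + disc)
        self._beta = self._k10 * self._k21 / self._alpha        # stable form
        with np.errstate(divide="ignore", invalid="ignore"):
            self._ass1 = self._R / self._k10
            self._ass2 = self._R * self._k12 / (self._k10 * self._k21)

        # propagate state and cumulative central-amount integral
        A1 = np.zeros((S + 1, n))
        A2 = np.zeros((S + 1, n))
        cum = np.zeros((S + 1, n))
        for sidx in range(S):
            dt = edges[sidx + 1] - edges[sidx]
            x1 = A1[sidx] - self._ass1[:, sidx]
            y1 = A2[sidx] - self._ass2[:, sidx]
            e11, e12, e21, e22, j11, j12 = self._flow(sidx, dt, slice(None))
            A1[sidx + 1] = self._ass1[:, sidx] + e11 * x1 + e12 * y1
            A2[sidx + 1] = self._ass2[:, sidx] + e21 * x1 + e22 * y1
            cum[sidx + 1] = cum[sidx] + self._ass1[:, sidx] * dt + j11 * x1 + j12 * y1
        self._A1, self._A2, self._cum = A1, A2, cum

    # -- matrix exponential / integral of the 2x2 disposition matrix -------

    def _flow(self, sidx, dt, sel):
        """Entries of E = exp(M dt) and first row of J = int_0^dt exp(M t) dt.

        ``sidx`` may be an int (one segment, subjects selected by ``sel``)
        or an index array aligned with ``sel`` for per-entry lookups.
        """
        a = self._alpha[sel, sidx]
        b = self._beta[sel, sidx]
        k10 = self._k10[sel, sidx]
        k12 = self._k12[sel, sidx]
        k21 = self._k21[sel, sidx]
        m11 = -(k10 + k12)
        m22 = -k21
        d = b - a
        ea = np.exp(-a * dt)
        eb = np.exp(-b * dt)
        degenerate = np.abs(d) < _HYBRID_DEGENERACY_TOL * a
        d_safe = np.where(degenerate, 1.0, d)
        e11 = (ea * (m11 + b) - eb * (m11 + a)) / d_safe
        e12 = (ea - eb) * k21 / d_safe
        e21 = (ea - eb) * k12 / d_safe
        e22 = (ea * (m22 + b) - eb * (m22 + a)) / d_safe
        ga = (1.0 - ea) / a
        gb = (1.0 - eb) / b
        j11 = (ga * (m11 + b) - gb * (m11 + a)) / d_safe
        j12 = (ga - gb) * k21 / d_safe
        if np.any(degenerate):
            # repeated hybrid constant: exp(M t) = e^{-a t} (I + (M + aI) t)
            n11 = m11 + a
            e11 = np.where(degenerate, ea * (1.0 + n11 * dt), e11)
            e12 = np.where(degenerate, ea * k21 * dt, e12)
            e21 = np.where(degenerate, ea * k12 * dt, e21)
            e22 = np.where(degenerate, ea * (1.0 + (m22 + a) * dt), e22)
            # int_0^dt t e^{-a t} dt
            it = (1.0 - ea * (1.0 + a * dt)) / (a * a)
            j11 = np.where(degenerate, ga + n11 * it, j11)
            j12 = np.where(degenerate, k21 * it, j12)
        return e11, e12, e21, e22, j11, j12

    # -- queries ------------------------------------------------------------

    def _locate(self, t):
        t = np.asarray(t, dtype=float)
        shape = t.shape
        if t.ndim <= 1:
            t2 = np.broadcast_to(t.reshape(1, -1), (self.n, t.size))
        elif t.ndim == 2 and t.shape[0] == self.n:
            t2 = t
        else:
            raise ValueError("query times must be scalar, 1-D, or (n, k)")
        if np.any((t2 < 0) | (t2 > self.horizon + 1e-9)):
            raise ValueError("query time outside [0, horizon]")
        idx = np.clip(np.searchsorted(self.edges, t2, side="right") - 1,
                      0, len(self.edges) - 2)
        return t2, idx, shape

    def conc(self, t):
        """Central-compartment concentration at time(s) t, mg/L."""
        t2, idx, shape = self._locate(t)
        rows = np.broadcast_to(np.arange(self.n)[:, None], idx.shape)
        dt = t2 - self.edges[idx]
        x1 = self._A1.T[rows, idx] - self._ass1[rows, idx]
        y1 = self._A2.T[rows, idx] - self._ass2[rows, idx]
        e11, e12, _, _, _, _ = self._flow(idx, dt, rows)
        a1 = self._ass1[rows, idx] + e11 * x1 + e12 * y1
        out = a1 / self.v1[:, None]
        return self._shape_out(out, shape)

    def auc_to(self, t):
        """AUC of the central concentration over [0, t], mg*h/L."""
        t2, idx, shape = self._locate(t)
        rows = np.broadcast_to(np.arange(self.n)[:, None], idx.shape)
        dt = t2 - self.edges[idx]
        x1 = self._A1.T[rows, idx] - self._ass1[rows, idx]
        y1 = self._A2.T[rows, idx] - self._ass2[rows, idx]
        _, _, _, _, j11, j12 = self._flow(idx, dt, rows)
        cum = self._cum.T[rows, idx] + self._ass1[rows, idx] * dt \
            + j11 * x1 + j12 * y1
        out = cum / self.v1[:, None]
        return self._shape_out(out, shape)

    def auc(self, t1, t2):
        """AUC over the window [t1, t2], mg*h/L."""
        if not t1 < t2:
            raise ValueError("AUC window requires t1 < t2")
        return self.auc_to(t2) - self.auc_to(t1)

    def _shape_out(self, out, shape):
        if shape == ():
            return out[:, 0] if self.n > 1 else float(out[0, 0])
        if len(shape) == 1:
            return out if self.n > 1 else out[0]
        return out


def solve_regimen(ind: IndividualParams, reg: Regimen) -> RegimenSolution:
    """Closed-form solution of one subject's regimen."""
    starts = np.array([e.start for e in reg.events])
    durations = np.array([e.duration for e in reg.events])
    occs = np.array([e.occ for e in reg.events], dtype=int)
    doses = np.array([e.dose for e in reg.events])
    kappa = None
    if ind.kappa_cl:
        kappa = np.array(ind.kappa_cl, dtype=float)[None, :]
        if kappa.shape[1] <= (occs.max(initial=0)):
            raise ValueError("regimen references occasions without a kappa value")
    return RegimenSolution(
        ind.cl, ind.v1, ind.q, ind.v2, starts, durations, occs, doses,
        reg.horizon, kappa=kappa,
    )


def concentration(ind: IndividualParams, reg: Regimen, t) -> float:
    """Central concentration for one subject at time(s) ``t``, mg/L."""
    return solve_regimen(ind, reg).conc(t)


def auc(ind: IndividualParams, reg: Regimen, t1: float, t2: float) -> float:
    """Exact AUC of the central concentration over [t1, t2], mg*h/L."""
    return float(np.asarray(solve_regimen(ind, reg).auc(t1, t2)))


def trough(ind: IndividualParams, reg: Regimen, t_dose: float) -> float:
    """Concentration immediately before the infusion starting at ``t_dose``.

    The solution is continuous, so the pre-dose trough equals the
    concentration evaluated at the dose time itself.
    """
    if not any(math.isclose(e.start, t_dose, abs_tol=1e-9) for e in reg.events):
        raise ValueError(f"t_dose={t_dose!r} is not an event start time")
    return float(np.asarray(concentration(ind, reg, t_dose)))
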