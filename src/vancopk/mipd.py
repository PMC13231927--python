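"""MAP (empirical-Bayes) individual estimation and dose forecasting.

Given fixed population parameters and one subject's dosing history and
measured concentrations, the conditional mode of the subject's random
effects minimizes

    sum_j [ (DV_j - f_j)^2 / (sigma^2 f_j^2) + ln(sigma^2 f_j^2) ]
        + eta' Omega^-1 eta + sum_occ kappa_occ^2 / omega_iov^2

i.e. the proportional-error residual term with the interaction term
ln(sigma^2 f^2) retained, plus the lognormal prior on the between-subject
(eta) and between-occasion (kappa) deviations.  This is the fixed-population
("MAXEVAL=0") individual estimation mode used for external validation and
for model-informed precision dosing.

The mode search is a damped Newton iteration with finite-difference
derivatives, vectorized over subjects that share an infusion schedule; the
population-fit module reuses that machinery for its conditional modes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .dataio import Subject, TdmDataset
from .popmodel import (
    IndividualParams,
    PopParams,
    Regimen,
    RegimenSolution,
    typical_params,
)

__all__ = [
    "Design",
    "ModeResult",
    "conditional_modes",
    "MapFit",
    "map_estimate",
    "DoseRecommendation",
    "forecast_and_adjust",
]

_F_FLOOR = 1e-12
_FD_STEP = 1e-4


# ---------------------------------------------------------------------------
# Batch design
# ---------------------------------------------------------------------------

@dataclass
class Design:
    """Prebuilt arrays for conditional estimation of n subjects sharing one
    infusion schedule (doses may differ per subject)."""

    ids: np.ndarray            # (n,)
    starts: np.ndarray         # (m,)
    durs: np.ndarray           # (m,)
    occs: np.ndarray           # (m,)
    doses: np.ndarray          # (n, m)
    horizon: float
    obs_t: np.ndarray          # (n, J) padded
    dv: np.ndarray             # (n, J) padded
    mask: np.ndarray           # (n, J) bool
    age: np.ndarray
    wt: np.ndarray
    scr: np.ndarray
    pma: np.ndarray
    n_occ: int

    @property
    def n(self) -> int:
        return len(self.ids)

    @classmethod
    def from_subjects(cls, subjects: Sequence[Subject]) -> "Design":
        s0 = subjects[0]
        starts = np.array([e.start for e in s0.regimen.events])
        durs = np.array([e.duration for e in s0.regimen.events])
        occs = np.array([e.occ for e in s0.regimen.events], dtype=int)
        for s in subjects[1:]:
            if (tuple(e.start for e in s.regimen.events) != tuple(starts)
                    or tuple(e.duration for e in s.regimen.events) != tuple(durs)
                    or tuple(e.occ for e in s.regimen.events) != tuple(occs)):
                raise ValueError("subjects do not share an infusion schedule")
        n = len(subjects)
        jmax = max(s.n_obs for s in subjects) or 1
        obs_t = np.zeros((n, jmax))
        dv = np.ones((n, jmax))
        mask = np.zeros((n, jmax), dtype=bool)
        doses = np.zeros((n, len(starts)))
        for i, s in enumerate(subjects):
            j = s.n_obs
            obs_t[i, :j] = s.obs_times
            dv[i, :j] = s.dv
            mask[i, :j] = True
            doses[i] = [e.dose for e in s.regimen.events]
        horizon = max(s.regimen.horizon for s in subjects)
        return cls(
            ids=np.array([s.id for s in subjects]),
            starts=starts, durs=durs, occs=occs, doses=doses, horizon=horizon,
            obs_t=obs_t, dv=dv, mask=mask,
            age=np.array([s.covariates.age for s in subjects]),
            wt=np.array([s.covariates.wt for s in subjects]),
            scr=np.array([s.covariates.scr for s in subjects]),
            pma=np.array([s.covariates.pma for s in subjects]),
            n_occ=int(occs.max(initial=0)) + 1,
        )

    @classmethod
    def from_dataset(cls, ds: TdmDataset) -> "Design":
        return cls.from_subjects(list(ds.subjects()))

    def typical(self, pop: PopParams):
        """Typical CL, V1, Q, V2 arrays under ``pop`` (vectorized)."""
        from .popmodel import f_mat, f_renal, f_size

        size = f_size(self.wt)
        cl = pop.tvcl * size * f_mat(self.pma, pop.hill, pop.tm50) \
            * f_renal(self.scr, self.age, pop.theta_scr)
        wfrac = self.wt / 70.0
        return cl, pop.tvv1 * wfrac, pop.tvq * size, pop.tvv2 * wfrac


def _active_dims(pop: PopParams, design: Design, estimate_iov: bool):
    """Indices (into the full [eta_cl, eta_v1, kappa_0..] layout) of random
    effects with positive variance; zero-variance dims stay fixed at 0."""
    dims, sds = [], []
    if pop.omega_cl > 0:
        dims.append(0)
        sds.append(pop.omega_cl)
    if pop.omega_v1 > 0:
        dims.append(1)
        sds.append(pop.omega_v1)
    if estimate_iov and pop.omega_iov_cl > 0:
        for k in range(design.n_occ):
            dims.append(2 + k)
            sds.append(pop.omega_iov_cl)
    return np.array(dims, dtype=int), np.array(sds)


def _h_batch(pop: PopParams, design: Design, eta_full: np.ndarray,
             typ=None) -> np.ndarray:
    """The MAP objective for every subject; eta_full is (n, 2 + n_occ)."""
    if pop.sigma_prop <= 0:
        raise ValueError("sigma_prop must be > 0 for estimation")
    if typ is None:
        typ = design.typical(pop)
    tcl, tv1, tq, tv2 = typ
    eta_full = np.clip(eta_full, -20.0, 20.0)
    cl = tcl * np.exp(eta_full[:, 0])
    v1 = tv1 * np.exp(eta_full[:, 1])
    kappa = eta_full[:, 2:2 + design.n_occ]
    sol = RegimenSolution(cl, v1, tq, tv2, design.starts, design.durs,
                          design.occs, design.doses, design.horizon,
                          kappa=kappa if design.n_occ else None)
    f = np.maximum(np.atleast_2d(sol.conc(design.obs_t)), _F_FLOOR)
    var = (pop.sigma_prop * f) ** 2
    res = ((design.dv - f) ** 2 / var + np.log(var)) * design.mask
    h = res.sum(axis=1)
    if pop.omega_cl > 0:
        h = h + eta_full[:, 0] ** 2 / pop.omega_cl ** 2
    if pop.omega_v1 > 0:
        h = h + eta_full[:, 1] ** 2 / pop.omega_v1 ** 2
    if design.n_occ and pop.omega_iov_cl > 0:
        h = h + (kappa ** 2).sum(axis=1) / pop.omega_iov_cl ** 2
    return h


@dataclass
class ModeResult:
    eta_full: np.ndarray       # (n, 2 + n_occ), inactive dims zero
    h: np.ndarray              # (n,) objective at the mode
    hess: np.ndarray           # (n, p, p) Hessian of h over active dims
    active_dims: np.ndarray    # (p,)
    n_iter: int


def _fd_grad_hess(fun, x, step=_FD_STEP):
    """Batched central finite-difference gradient and Hessian.

    ``fun`` maps (n, p) -> (n,); returns g (n, p), H (n, p, p).
    """
    n, p = x.shape
    f0 = fun(x)
    g = np.zeros((n, p))
    H = np.zeros((n, p, p))
    fp = np.zeros((n, p))
    fm = np.zeros((n, p))
    for i in range(p):
        e = np.zeros(p)
        e[i] = step
        fp[:, i] = fun(x + e)
        fm[:, i] = fun(x - e)
        g[:, i] = (fp[:, i] - fm[:, i]) / (2 * step)
        H[:, i, i] = (fp[:, i] - 2 * f0 + fm[:, i]) / step ** 2
    for i in range(p):
        for j in range(i + 1, p):
            ei = np.zeros(p); ei[i] = step
            ej = np.zeros(p); ej[j] = step
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[:, i, j] = H[:, j, i] = (fpp - fpm - fmp + fmm) / (4 * step ** 2)
    return f0, g, H


def conditional_modes(pop: PopParams, design: Design,
                      estimate_iov: bool = True,
                      eta_init: np.ndarray | None = None,
                      multistart: bool = True,
                      tol: float = 1e-8,
                      max_iter: int = 60) -> ModeResult:
    """Batched conditional-mode (MAP) search for every subject in a design.

    Damped Newton on the active random-effect dimensions; starts from zero
    and, when ``multistart``, from +/-1 prior SD, keeping each subject's
    best mode.  ``eta_init`` (n, p_active) warm-starts instead.
    """
    dims, sds = _active_dims(pop, design, estimate_iov)
    p = len(dims)
    n = design.n
    width = 2 + design.n_occ
    typ = design.typical(pop)
    if p == 0 or not design.mask.any():
        eta_full = np.zeros((n, width))
        h = _h_batch(pop, design, eta_full, typ)
        return ModeResult(eta_full, h, np.zeros((n, 0, 0)), dims, 0)

    def fun(x):
        full = np.zeros((n, width))
        full[:, dims] = x
        return _h_batch(pop, design, full, typ)

    starts = []
    if eta_init is not None:
        starts.append(np.asarray(eta_init, dtype=float).reshape(n, p))
    else:
        starts.append(np.zeros((n, p)))
        if multistart:
            starts.append(np.broadcast_to(sds, (n, p)).copy())
            starts.append(-np.broadcast_to(sds, (n, p)).copy())

    best_x = None
    best_h = np.full(n, np.inf)
    total_iter = 0
    for x0 in starts:
        x = x0.copy()
        h = fun(x)
        for it in range(max_iter):
            total_iter += 1
            h0, g, H = _fd_grad_hess(fun, x)
            # make the per-subject Hessians safely positive definite
            absmax = np.abs(H).max(axis=(1, 2))
            lam = np.maximum(0.0, -np.linalg.eigvalsh(H).min(axis=1)) \
                + 1e-9 * absmax + 1e-8
            Hd = H + lam[:, None, None] * np.eye(p)
            try:
                step_vec = -np.linalg.solve(Hd, g[:, :, None])[:, :, 0]
            except np.linalg.LinAlgError:
                step_vec = -np.einsum(
                    "nij,nj->ni", np.linalg.pinv(Hd), g)
            # cap the step: far from the mode the quadratic model overshoots
            norm = np.linalg.norm(step_vec, axis=1)
            too_big = norm > 4.0
            if too_big.any():
                step_vec[too_big] *= (4.0 / norm[too_big])[:, None]
            scale = np.ones(n)
            improved = np.zeros(n, dtype=bool)
            x_new, h_new = x.copy(), h0.copy()
            for _ in range(8):
                trial = x + scale[:, None] * step_vec
                ht = fun(trial)
                better = ht < h_new - 1e-14
                todo = better & ~improved
                x_new[todo] = trial[todo]
                h_new[todo] = ht[todo]
                improved |= better
                if improved.all():
                    break
                scale = np.where(improved, scale, scale * 0.5)
            delta = h - h_new
            x, h = x_new, h_new
            if delta.max(initial=0.0) < tol and np.abs(g).max() < 1e-5:
                break
        replace = h < best_h
        if best_x is None:
            best_x, best_h = x, h
        else:
            best_x[replace] = x[replace]
            best_h[replace] = h[replace]

    _, _, H = _fd_grad_hess(fun, best_x)
    eta_full = np.zeros((n, width))
    eta_full[:, dims] = best_x
    return ModeResult(eta_full, best_h, H, dims, total_iter)


# ---------------------------------------------------------------------------
# Single-subject MAP fit
# ---------------------------------------------------------------------------

@dataclass
class MapFit:
    """Mode of one subject's random effects under fixed population parameters."""

    subject: Subject
    params: IndividualParams
    eta_cl: float
    eta_v1: float
    kappa: tuple[float, ...]
    objective: float
    ipred: np.ndarray          # individual predictions at observation times
    auc_0_24: float
    auc_24_48: float

    @property
    def cl(self) -> float:
        return self.params.cl


def map_estimate(pop: PopParams, subject: Subject,
                 estimate_iov: bool = True, tol: float = 1e-8) -> MapFit:
    """MAP random-effect estimate for one subject.

    With no (usable) observations the prior mode (all zeros) is returned and
    the prediction is the population prediction.  Non-positive DV records
    are rejected.
    """
    good = subject.dv > 0
    if not good.all():
        subject = Subject(
            id=subject.id, covariates=subject.covariates,
            regimen=subject.regimen,
            obs_times=subject.obs_times[good], dv=subject.dv[good],
            obs_occ=subject.obs_occ[good],
        )
    design = Design.from_subjects([subject])
    mode = conditional_modes(pop, design, estimate_iov=estimate_iov, tol=tol)
    dims = mode.active_dims
    width = 2 + design.n_occ

    # polish the Newton mode with a derivative-free pass (robust near kinks)
    if len(dims) and design.mask.any():
        def h1(x):
            full = np.zeros((1, width))
            full[0, dims] = x
            return float(_h_batch(pop, design, full)[0])

        res = minimize(h1, mode.eta_full[0, dims], method="Nelder-Mead",
                       options=dict(fatol=tol, xatol=1e-9, maxfev=2000))
        if res.fun < mode.h[0]:
            mode.eta_full[0, dims] = res.x
            mode.h[0] = res.fun

    eta = mode.eta_full[0]
    typ = typical_params(pop, subject.covariates)
    kappa = tuple(eta[2:2 + design.n_occ])
    ind = IndividualParams(
        cl=typ.cl * float(np.exp(eta[0])),
        v1=typ.v1 * float(np.exp(eta[1])),
        q=typ.q, v2=typ.v2,
        eta_cl=float(eta[0]), eta_v1=float(eta[1]), kappa_cl=kappa,
    )
    reg = subject.regimen
    horizon = max(reg.horizon, 48.0)
    reg48 = Regimen(reg.events, horizon)
    from .popmodel import solve_regimen

    sol = solve_regimen(ind, reg48)
    if subject.n_obs:
        ipred = np.atleast_1d(sol.conc(subject.obs_times))
    else:
        ipred = np.array([])
    a = np.atleast_1d(sol.auc_to(np.array([24.0, 48.0])))
    return MapFit(
        subject=subject, params=ind,
        eta_cl=float(eta[0]), eta_v1=float(eta[1]), kappa=kappa,
        objective=float(mode.h[0]), ipred=ipred,
        auc_0_24=float(a[0]), auc_24_48=float(a[1] - a[0]),
    )


@dataclass(frozen=True)
class DoseRecommendation:
    daily_mg: float
    per_interval_mg: float
    per_interval_mg_per_kg: float
    interval_h: float
    predicted_daily_auc: float
    target_auc: float


def forecast_and_adjust(fit: MapFit, target_auc: float = 525.0,
                        interval_h: float = 6.0) -> DoseRecommendation:
    """Maintenance dose putting the predicted steady-state daily AUC at the
    window midpoint (default 525 mg*h/L): daily dose = target x CL.

    Between-occasion variability of future occasions is ignored (its
    expectation is the between-subject mode).
    """
    daily = target_auc * fit.cl
    per_int = round(daily / (24.0 / interval_h))
    return DoseRecommendation(
        daily_mg=daily,
        per_interval_mg=per_int,
        per_interval_mg_per_kg=per_int / fit.subject.covariates.wt,
        interval_h=interval_h,
        predicted_daily_auc=per_int * (24.0 / interval_h) / fit.cl,
        target_auc=target_auc,
    )
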