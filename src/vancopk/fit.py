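"""Population parameter estimation (conditional-mode marginal likelihood).

The marginal likelihood of each subject's data is approximated by the
Laplace method expanded at the conditional mode of the random effects, with
the interaction term (residual variance evaluated at the conditional
prediction) retained — the first-order-conditional-with-interaction family
of estimators at desk scale.  Writing h(eta) for the MAP objective of
:mod:`vancopk.mipd` (residual + prior terms), the per-subject contribution
to the -2 log marginal likelihood is

    OFV_i = h(eta_hat) + ln|Omega| + ln det( 0.5 * d2h/deta2 |_(eta_hat) )

with the additive n_obs * ln(2*pi) constant omitted.  Random-effect
dimensions whose variance is zero drop out of both the mode search and the
correction terms, so at Omega -> 0 the objective collapses to the residual
-2LL of the typical model.

Also here: the population fitter (Nelder-Mead over log-transformed
parameters with a warm-started conditional-mode cache) and the
nonparametric subject-level bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .dataio import TdmDataset
from .mipd import Design, _active_dims, conditional_modes
from .popmodel import PopParams

__all__ = [
    "FitResult",
    "foce_objective",
    "fit_population",
    "bootstrap",
    "DEFAULT_FIXED",
]

#: parameters held fixed by default: the maturation shape (externally fixed
#: in the source model) — callers typically also fix what their sampling
#: design cannot inform (e.g. peripheral parameters under sparse sampling)
DEFAULT_FIXED = frozenset({"hill", "tm50"})

_ESTIMABLE = ("tvcl", "tvv1", "tvq", "tvv2", "theta_scr",
              "omega_cl", "omega_v1", "omega_iov_cl", "sigma_prop")

_PENALTY = 1e10


@dataclass
class FitResult:
    """Point estimates, objective, and per-subject conditional modes."""

    params: PopParams
    objective: float
    converged: bool
    n_evals: int
    modes: pd.DataFrame | None = None
    se: dict | None = None


def _designs_for(ds_or_design) -> list[Design]:
    if isinstance(ds_or_design, Design):
        return [ds_or_design]
    ds = ds_or_design
    if ds.is_regular():
        return [Design.from_dataset(ds)]
    return [Design.from_subjects([s]) for s in ds.subjects()]


def foce_objective(pop: PopParams, dataset, estimate_iov: bool = True,
                   warm: dict | None = None, return_modes: bool = False):
    """Approximate -2 log marginal likelihood of a dataset under ``pop``.

    ``warm`` is an optional mutable cache mapping design index to the last
    conditional modes; passing the same dict across calls warm-starts the
    inner mode searches (used heavily by :func:`fit_population`).
    """
    designs = _designs_for(dataset)
    total = 0.0
    mode_rows = []
    for di, design in enumerate(designs):
        dims, sds = _active_dims(pop, design, estimate_iov)
        init = warm.get(di) if warm is not None else None
        if init is not None and init.shape != (design.n, len(dims)):
            init = None
        try:
            mode = conditional_modes(pop, design, estimate_iov=estimate_iov,
                                     eta_init=init,
                                     multistart=init is None)
        except (FloatingPointError, np.linalg.LinAlgError):
            return _PENALTY if not return_modes else (_PENALTY, None)
        if warm is not None:
            warm[di] = mode.eta_full[:, dims].copy()
        contrib = mode.h.copy()
        if len(dims):
            half_hess = 0.5 * mode.hess
            sign, logdet = np.linalg.slogdet(half_hess)
            if np.any(sign <= 0):
                # indefinite curvature at a reported mode: penalize softly
                logdet = np.where(sign <= 0, 50.0, logdet)
            contrib = contrib + logdet + 2.0 * np.log(sds).sum()
        if not np.all(np.isfinite(contrib)):
            return _PENALTY if not return_modes else (_PENALTY, None)
        total += float(contrib.sum())
        if return_modes:
            for i in range(design.n):
                mode_rows.append(dict(
                    ID=int(design.ids[i]),
                    eta_cl=mode.eta_full[i, 0],
                    eta_v1=mode.eta_full[i, 1],
                    **{f"kappa_{k}": mode.eta_full[i, 2 + k]
                       for k in range(design.n_occ)},
                    ofv_i=contrib[i],
                ))
    if return_modes:
        return total, pd.DataFrame(mode_rows)
    return total


def fit_population(dataset, init: PopParams | None = None,
                   fixed: frozenset = DEFAULT_FIXED,
                   estimate_iov: bool = True,
                   maxfev: int = 600,
                   fatol: float = 1e-3) -> FitResult:
    """Minimize the marginal-likelihood objective over the unfixed fields.

    Positive parameters are log-transformed; ``fixed`` names PopParams
    fields held at their ``init`` values (the maturation shape parameters
    always are).  Non-convergence returns the best-found estimates with
    ``converged=False``.
    """
    init = init or PopParams()
    free = [p for p in _ESTIMABLE if p not in fixed]
    if not free:
        obj = foce_objective(init, dataset, estimate_iov=estimate_iov)
        return FitResult(init, obj, True, 1)
    for name in free:
        if getattr(init, name) <= 0:
            raise ValueError(f"cannot log-transform {name} initialized <= 0")
    x0 = np.log([getattr(init, name) for name in free])
    designs = _designs_for(dataset)
    warm: dict = {}
    n_eval = 0

    def objective(x):
        nonlocal n_eval
        n_eval += 1
        if np.any(np.abs(x) > 20):
            return _PENALTY
        pop = init.replace(**{n: float(np.exp(v)) for n, v in zip(free, x)})
        return foce_objective(pop, designs[0] if len(designs) == 1 else dataset,
                              estimate_iov=estimate_iov, warm=warm)

    res = minimize(objective, x0, method="Nelder-Mead",
                   options=dict(maxfev=maxfev, fatol=fatol, xatol=1e-4))
    est = init.replace(**{n: float(np.exp(v)) for n, v in zip(free, res.x)})
    obj, modes = foce_objective(est, dataset, estimate_iov=estimate_iov,
                                warm=warm, return_modes=True)
    return FitResult(params=est, objective=obj,
                     converged=bool(res.success), n_evals=n_eval, modes=modes)


def bootstrap(dataset: TdmDataset, n_reps: int = 300, seed=0,
              init: PopParams | None = None,
              fixed: frozenset = DEFAULT_FIXED,
              estimate_iov: bool = True,
              maxfev: int = 300) -> pd.DataFrame:
    """Nonparametric bootstrap: resample subjects with replacement, refit.

    Returns one row per estimated parameter with the median and the
    2.5th/97.5th percentiles over converged replicates; the attrs carry the
    replicate exclusion rate.  ``n_reps`` well below the customary 300 is
    fine at desk scale.
    """
    rng = np.random.default_rng(seed)
    ids = dataset.subject_ids
    free = [p for p in _ESTIMABLE if p not in fixed]
    rows = []
    n_failed = 0
    for rep in range(n_reps):
        pick = rng.choice(ids, size=len(ids), replace=True)
        parts = []
        for new_id, sid in enumerate(pick, start=1):
            part = dataset.df[dataset.df["ID"] == sid].copy()
            part["ID"] = new_id
            parts.append(part)
        ds = TdmDataset(pd.concat(parts, ignore_index=True))
        result = fit_population(ds, init=init, fixed=fixed,
                                estimate_iov=estimate_iov, maxfev=maxfev)
        if not np.isfinite(result.objective) or result.objective >= _PENALTY:
            n_failed += 1
            continue
        rows.append({p: getattr(result.params, p) for p in free})
    if not rows:
        raise RuntimeError("every bootstrap replicate failed")
    reps = pd.DataFrame(rows)
    out = pd.DataFrame({
        "parameter": free,
        "median": [reps[p].median() for p in free],
        "p2.5": [reps[p].quantile(0.025) for p in free],
        "p97.5": [reps[p].quantile(0.975) for p in free],
    })
    out.attrs["n_reps"] = n_reps
    out.attrs["n_excluded"] = n_failed
    out.attrs["exclusion_rate"] = n_failed / n_reps
    return out
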