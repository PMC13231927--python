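"""Model-evaluation diagnostics: GoF tables, CWRES, and pcVPC.

Conditional weighted residuals decorrelate the observation vector using the
model linearized at each subject's conditional mode:

    E[DV] ~ f(eta_hat) - F eta_hat
    Cov   ~ F Omega F' + diag(sigma^2 f(eta_hat)^2)
    CWRES = L^-1 (DV - E[DV]),   L L' = Cov

and are approximately standard normal under a correct model.  The
prediction-corrected VPC normalizes every observation (and every simulated
replicate) by its subject's population prediction relative to the bin
median prediction, then compares observed percentiles per
time-after-previous-dose bin with the simulation-based confidence bands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import TdmDataset
from .mipd import Design, _active_dims, conditional_modes
from .popmodel import PopParams, RegimenSolution

__all__ = ["VpcConfig", "cwres", "gof_tables", "pcvpc"]

log = logging.getLogger(__name__)

_RIDGE = 1e-10
_MIN_BIN = 5


def _predict(pop: PopParams, design: Design, eta_full: np.ndarray) -> np.ndarray:
    """Model predictions (n, J) at the design's observation times."""
    tcl, tv1, tq, tv2 = design.typical(pop)
    cl = tcl * np.exp(eta_full[:, 0])
    v1 = tv1 * np.exp(eta_full[:, 1])
    kappa = eta_full[:, 2:2 + design.n_occ]
    sol = RegimenSolution(cl, v1, tq, tv2, design.starts, design.durs,
                          design.occs, design.doses, design.horizon,
                          kappa=kappa if design.n_occ else None)
    return np.atleast_2d(sol.conc(design.obs_t))


def _designs(ds: TdmDataset) -> list[Design]:
    if ds.is_regular():
        return [Design.from_dataset(ds)]
    return [Design.from_subjects([s]) for s in ds.subjects()]


def cwres(pop: PopParams, dataset: TdmDataset,
          estimate_iov: bool = True) -> pd.DataFrame:
    """Conditional weighted residuals, one row per observation."""
    rows = []
    for design in _designs(dataset):
        dims, sds = _active_dims(pop, design, estimate_iov)
        mode = conditional_modes(pop, design, estimate_iov=estimate_iov)
        f_hat = _predict(pop, design, mode.eta_full)
        # gradient of f wrt active random effects, by central differences
        p = len(dims)
        F = np.zeros(f_hat.shape + (p,))
        step = 1e-4
        for a, d in enumerate(dims):
            e = np.zeros_like(mode.eta_full)
            e[:, d] = step
            F[:, :, a] = (_predict(pop, design, mode.eta_full + e)
                          - _predict(pop, design, mode.eta_full - e)) / (2 * step)
        eta_act = mode.eta_full[:, dims]
        mean = f_hat - np.einsum("nja,na->nj", F, eta_act)
        omega = np.diag(sds ** 2)
        for i in range(design.n):
            m = design.mask[i]
            if not m.any():
                continue
            Fi = F[i][m]
            cov = Fi @ omega @ Fi.T + np.diag(
                (pop.sigma_prop * f_hat[i][m]) ** 2)
            try:
                L = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                log.warning("singular CWRES covariance for subject %s; "
                            "ridged", design.ids[i])
                L = np.linalg.cholesky(cov + _RIDGE * np.eye(len(cov)))
            res = np.linalg.solve(L, design.dv[i][m] - mean[i][m])
            for t, y, c in zip(design.obs_t[i][m], design.dv[i][m], res):
                rows.append(dict(ID=int(design.ids[i]), TIME=float(t),
                                 DV=float(y), CWRES=float(c)))
    return pd.DataFrame(rows)


def gof_tables(pop: PopParams, dataset: TdmDataset,
               estimate_iov: bool = True) -> pd.DataFrame:
    """Population (PRED) and individual (IPRED) predictions per observation.

    PRED uses zero random effects; IPRED the conditional modes.  The attrs
    carry identity-line regression slopes/intercepts for both.
    """
    rows = []
    for design in _designs(dataset):
        mode = conditional_modes(pop, design, estimate_iov=estimate_iov)
        pred = _predict(pop, design, np.zeros_like(mode.eta_full))
        ipred = _predict(pop, design, mode.eta_full)
        for i in range(design.n):
            m = design.mask[i]
            for t, y, pr, ip in zip(design.obs_t[i][m], design.dv[i][m],
                                    pred[i][m], ipred[i][m]):
                rows.append(dict(ID=int(design.ids[i]), TIME=float(t),
                                 DV=float(y), PRED=float(pr), IPRED=float(ip)))
    out = pd.DataFrame(rows)
    for col in ("PRED", "IPRED"):
        slope, intercept = np.polyfit(out[col], out["DV"], 1)
        out.attrs[f"{col.lower()}_slope"] = float(slope)
        out.attrs[f"{col.lower()}_intercept"] = float(intercept)
    return out


@dataclass
class VpcConfig:
    """Prediction-corrected VPC settings."""

    n_sim: int = 1000
    n_bins: int = 6
    bin_edges: np.ndarray | None = None      # on time-after-previous-dose, h
    percentiles: tuple[float, ...] = (5.0, 50.0, 95.0)
    ci: float = 0.95
    stratify_mode: bool = False              # intermittent vs continuous

    def __post_init__(self) -> None:
        if tuple(self.percentiles) != tuple(sorted(self.percentiles)):
            raise ValueError("percentiles must be ordered")
        if not 0 < self.ci < 1:
            raise ValueError("ci must lie in (0, 1)")


def _time_after_dose(design: Design) -> np.ndarray:
    """Time since the most recent infusion start, per observation (n, J)."""
    idx = np.clip(np.searchsorted(design.starts, design.obs_t, side="right") - 1,
                  0, None)
    return design.obs_t - design.starts[np.clip(idx, 0, len(design.starts) - 1)]


def _infusion_mode(design: Design) -> np.ndarray:
    """'continuous' when a single infusion covers >=90% of the horizon."""
    if len(design.starts) == 1 and design.durs[0] >= 0.9 * design.horizon:
        return np.full(design.n, "continuous")
    return np.full(design.n, "intermittent")


def pcvpc(pop: PopParams, dataset: TdmDataset, cfg: VpcConfig | None = None,
          seed=0, estimate_iov: bool = True) -> pd.DataFrame:
    """Prediction-corrected visual predictive check summaries.

    Returns one row per (stratum, bin): observed corrected percentiles and
    the simulation confidence interval of each percentile across ``n_sim``
    replicates simulated from the model (random effects + proportional
    residual error).  Bins with fewer than five observations are merged
    leftward.
    """
    cfg = cfg or VpcConfig()
    rng = np.random.default_rng(seed)

    tad_l, pred_l, dv_l, strat_l = [], [], [], []
    sims_l = []
    for design in _designs(dataset):
        m = design.mask
        pred = _predict(pop, design, np.zeros((design.n, 2 + design.n_occ)))
        tad_l.append(_time_after_dose(design)[m])
        pred_l.append(pred[m])
        dv_l.append(design.dv[m])
        strat = np.broadcast_to(_infusion_mode(design)[:, None], m.shape)[m]
        strat_l.append(strat)
        # simulate replicates on the same design
        reps = np.empty((cfg.n_sim, int(m.sum())))
        tcl, tv1, tq, tv2 = design.typical(pop)
        for r in range(cfg.n_sim):
            eta_cl = rng.normal(0, pop.omega_cl, design.n)
            eta_v1 = rng.normal(0, pop.omega_v1, design.n)
            kap = rng.normal(0, pop.omega_iov_cl, (design.n, max(design.n_occ, 1)))
            sol = RegimenSolution(tcl * np.exp(eta_cl), tv1 * np.exp(eta_v1),
                                  tq, tv2, design.starts, design.durs,
                                  design.occs, design.doses, design.horizon,
                                  kappa=kap)
            f = np.atleast_2d(sol.conc(design.obs_t))
            dv = f * (1 + pop.sigma_prop * rng.normal(size=f.shape))
            reps[r] = dv[m]
        sims_l.append(reps)

    tad = np.concatenate(tad_l)
    pred = np.concatenate(pred_l)
    dv = np.concatenate(dv_l)
    strata = np.concatenate(strat_l)
    sims = np.concatenate(sims_l, axis=1)

    out_rows = []
    for stratum in (np.unique(strata) if cfg.stratify_mode else ["all"]):
        sel = strata == stratum if cfg.stratify_mode else np.ones(len(tad), bool)
        t, p_sel, y, s = tad[sel], pred[sel], dv[sel], sims[:, sel]
        if cfg.bin_edges is not None:
            edges = np.asarray(cfg.bin_edges, dtype=float)
        else:
            qs = np.linspace(0, 1, cfg.n_bins + 1)
            edges = np.unique(np.quantile(t, qs))
        edges[0], edges[-1] = min(edges[0], t.min()), max(edges[-1], t.max() + 1e-9)
        bin_idx = np.clip(np.searchsorted(edges, t, side="right") - 1,
                          0, len(edges) - 2)
        # merge small bins leftward
        for b in range(len(edges) - 1):
            if 0 < (bin_idx == b).sum() < _MIN_BIN and b > 0:
                log.info("merging sparse VPC bin %d leftward", b)
                bin_idx[bin_idx == b] = b - 1
        lo_q, hi_q = (1 - cfg.ci) / 2, 1 - (1 - cfg.ci) / 2
        for b in np.unique(bin_idx):
            inb = bin_idx == b
            med_pred = np.median(p_sel[inb])
            corr = med_pred / p_sel[inb]
            y_pc = y[inb] * corr
            s_pc = s[:, inb] * corr[None, :]
            row = dict(stratum=stratum, bin=int(b),
                       t_lo=float(edges[b]), t_hi=float(edges[min(b + 1, len(edges) - 1)]),
                       n_obs=int(inb.sum()))
            for pc in cfg.percentiles:
                row[f"obs_p{pc:g}"] = float(np.percentile(y_pc, pc))
                sim_pcs = np.percentile(s_pc, pc, axis=1)
                row[f"sim_p{pc:g}_lo"] = float(np.quantile(sim_pcs, lo_q))
                row[f"sim_p{pc:g}_med"] = float(np.median(sim_pcs))
                row[f"sim_p{pc:g}_hi"] = float(np.quantile(sim_pcs, hi_q))
            out_rows.append(row)
    return pd.DataFrame(out_rows)
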