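"""MAP individual estimation and dose forecasting."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from vancopk import map_estimate, forecast_and_adjust
from vancopk.cohort import sample_reference_cohort, synthesize_tdm
from vancopk.dataio import Subject
from vancopk.mipd import Design, _h_batch, conditional_modes
from vancopk.popmodel import (
    InfusionEvent,
    Regimen,
    SubjectCovariates,
    solve_regimen,
    typical_params,
)


def _subject(cov, regimen, times, dv, sid=1):
    occs = np.zeros(len(times), dtype=int)
    return Subject(id=sid, covariates=cov, regimen=regimen,
                   obs_times=np.asarray(times, dtype=float),
                   dv=np.asarray(dv, dtype=float), obs_occ=occs)


@pytest.fixture
def child_cov():
    return SubjectCovariates(age=4.0, wt=16.0, scr=28.0)


class TestMapEstimate:
    def test_zero_observations_returns_prior_mode(self, pop, child_cov):
        reg = Regimen.intermittent(240.0, horizon=48.0)
        s = _subject(child_cov, reg, [], [])
        fit = map_estimate(pop, s)
        assert fit.eta_cl == 0.0 and fit.eta_v1 == 0.0
        assert all(k == 0.0 for k in fit.kappa)
        typ = typical_params(pop, child_cov)
        assert fit.cl == pytest.approx(typ.cl)

    def test_nonpositive_dv_rejected(self, pop, child_cov):
        reg = Regimen.intermittent(240.0, horizon=48.0)
        s = _subject(child_cov, reg, [5.0, 11.0], [-1.0, 8.0])
        fit = map_estimate(pop, s)
        assert len(fit.subject.dv) == 1

    def test_noise_free_recovery_of_known_eta(self, pop):
        # tiny residual error: the likelihood pins eta to the truth
        quiet = pop.replace(sigma_prop=1e-6, omega_iov_cl=0.0)
        cohort = sample_reference_cohort(4, seed=20)
        ds = synthesize_tdm(quiet, cohort, seed=21, lloq=0.0)
        for sid in ds.subject_ids:
            s = ds.subject(sid)
            if s.n_obs < 2:
                continue
            fit = map_estimate(quiet, s)
            row = ds.truth[ds.truth.ID == sid].iloc[0]
            assert fit.eta_cl == pytest.approx(row.eta_cl, abs=1e-3)
            assert fit.eta_v1 == pytest.approx(row.eta_v1, abs=1e-3)

    def test_vanishing_prior_approaches_least_squares(self, pop, child_cov):
        reg = Regimen.intermittent(240.0, horizon=48.0)
        ind = typical_params(pop, child_cov)
        times = np.array([1.05, 5.9, 23.9, 47.9])
        truth_mult = 1.35
        from vancopk.popmodel import IndividualParams

        shifted = IndividualParams(cl=ind.cl * truth_mult, v1=ind.v1,
                                   q=ind.q, v2=ind.v2)
        dv = np.atleast_1d(solve_regimen(shifted, reg).conc(times))
        s = _subject(child_cov, reg, times, dv)
        flat = pop.replace(omega_cl=50.0, omega_v1=0.0, omega_iov_cl=0.0)
        fit = map_estimate(flat, s)

        # least-squares-in-CL oracle under the same weighted residual metric
        def sse(log_mult):
            trial = IndividualParams(cl=ind.cl * np.exp(log_mult), v1=ind.v1,
                                     q=ind.q, v2=ind.v2)
            f = np.atleast_1d(solve_regimen(trial, reg).conc(times))
            return float(np.sum((dv - f) ** 2 / (pop.sigma_prop * f) ** 2
                                + np.log((pop.sigma_prop * f) ** 2)))

        res = minimize_scalar(sse, bounds=(-1.0, 1.0), method="bounded",
                              options=dict(xatol=1e-10))
        # the prior has vanished: MAP coincides with the individual fit
        # (which is offset from the noise-free truth by the ln(sigma^2 f^2)
        # interaction term at this residual magnitude)
        assert fit.eta_cl == pytest.approx(res.x, abs=1e-3)
        assert abs(np.exp(fit.eta_cl) - truth_mult) < 0.1

    def test_multistart_objective_not_worse_than_zero_start(self, pop):
        cohort = sample_reference_cohort(6, seed=22)
        ds = synthesize_tdm(pop, cohort, seed=23)
        for sid in ds.subject_ids[:3]:
            s = ds.subject(sid)
            design = Design.from_subjects([s])
            fit = map_estimate(pop, s)
            width = 2 + design.n_occ
            h0 = float(_h_batch(pop, design, np.zeros((1, width)))[0])
            assert fit.objective <= h0 + 1e-9


class TestCalibration:
    def test_map_auc_rank_correlates_with_truth(self, pop):
        """Two troughs per subject must rank steady-state exposure well."""
        from scipy.stats import spearmanr

        cohort = sample_reference_cohort(500, seed=24)

        def two_troughs(rng, reg):
            return np.array([23.9, 47.9])

        ds = synthesize_tdm(pop, cohort, sampling_policy=two_troughs,
                            seed=25, lloq=0.0)
        design = Design.from_dataset(ds)
        mode = conditional_modes(pop, design)
        tcl, tv1, tq, tv2 = design.typical(pop)
        from vancopk.popmodel import RegimenSolution

        sol = RegimenSolution(
            tcl * np.exp(mode.eta_full[:, 0]),
            tv1 * np.exp(mode.eta_full[:, 1]), tq, tv2,
            design.starts, design.durs, design.occs, design.doses,
            design.horizon, kappa=mode.eta_full[:, 2:2 + design.n_occ])
        a = np.atleast_2d(sol.auc_to(np.array([24.0, 48.0])))
        map_auc = a[:, 1] - a[:, 0]

        truth = ds.truth.set_index("ID").loc[design.ids]
        sol_t = RegimenSolution(
            truth.cl.to_numpy(), truth.v1.to_numpy(),
            truth.q.to_numpy(), truth.v2.to_numpy(),
            design.starts, design.durs, design.occs, design.doses,
            design.horizon, kappa=truth[["kappa_0"]].to_numpy())
        at = np.atleast_2d(sol_t.auc_to(np.array([24.0, 48.0])))
        true_auc = at[:, 1] - at[:, 0]
        rho = spearmanr(map_auc, true_auc).statistic
        assert rho > 0.8


class TestForecast:
    def test_dose_equals_target_auc_times_clearance(self, pop, child_cov):
        reg = Regimen.intermittent(240.0, horizon=48.0)
        s = _subject(child_cov, reg, [], [])
        fit = map_estimate(pop, s)
        rec = forecast_and_adjust(fit)
        assert rec.daily_mg == pytest.approx(525.0 * fit.cl)
        assert rec.per_interval_mg == round(525.0 * fit.cl / 4.0)

    def test_doubled_clearance_doubles_recommendation(self, pop, child_cov):
        reg = Regimen.intermittent(240.0, horizon=48.0)
        fit = map_estimate(pop, _subject(child_cov, reg, [], []))
        rec1 = forecast_and_adjust(fit)
        import dataclasses

        from vancopk.popmodel import IndividualParams

        doubled = dataclasses.replace(
            fit, params=IndividualParams(cl=2 * fit.cl, v1=fit.params.v1,
                                         q=fit.params.q, v2=fit.params.v2))
        rec2 = forecast_and_adjust(doubled)
        assert rec2.daily_mg == pytest.approx(2 * rec1.daily_mg)

    def test_recommended_dose_hits_window_ignoring_iov(self, pop, child_cov):
        reg = Regimen.intermittent(240.0, horizon=48.0)
        fit = map_estimate(pop, _subject(child_cov, reg, [], []))
        rec = forecast_and_adjust(fit)
        assert 400.0 <= rec.predicted_daily_auc <= 650.0
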