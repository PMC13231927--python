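import numpy as np
import pytest

from vancopk import (
    IndividualParams,
    InfusionEvent,
    PopParams,
    Regimen,
    SubjectCovariates,
)


@pytest.fixture(scope="session")
def pop() -> PopParams:
    return PopParams.final_model()


@pytest.fixture
def adult_cov(pop) -> SubjectCovariates:
    """70 kg reference subject: fully mature, age-standard creatinine."""
    from vancopk import scr_std

    return SubjectCovariates(age=16.5, wt=70.0, scr=scr_std(16.5), pma=900.0)


@pytest.fixture
def simple_ind() -> IndividualParams:
    return IndividualParams(cl=3.0, v1=40.0, q=1.0, v2=150.0)


@pytest.fixture
def q6h_regimen() -> Regimen:
    return Regimen.intermittent(450.0, horizon=48.0)


def random_individual(rng) -> IndividualParams:
    return IndividualParams(
        cl=rng.uniform(0.3, 8.0),
        v1=rng.uniform(5.0, 90.0),
        q=rng.uniform(0.2, 3.0),
        v2=rng.uniform(20.0, 300.0),
    )


def random_regimen(rng, max_events: int = 6) -> Regimen:
    t = 0.0
    events = []
    for _ in range(rng.integers(1, max_events + 1)):
        t += rng.uniform(0.0, 12.0)
        events.append(InfusionEvent(t, rng.uniform(50.0, 800.0),
                                    rng.uniform(0.25, 3.0)))
    return Regimen(tuple(events), horizon=t + rng.uniform(10.0, 40.0))


def ode_concentration(ind: IndividualParams, reg: Regimen, times) -> np.ndarray:
    """Independent oracle: stiff-tolerance numerical integration of the
    two-compartment mass balance."""
    from scipy.integrate import solve_ivp

    k10, k12, k21 = ind.k10, ind.k12, ind.k21
    events = reg.events

    def rate(t):
        return sum(e.rate for e in events
                   if e.start <= t < e.start + e.duration)

    def rhs(t, y):
        return [-(k10 + k12) * y[0] + k21 * y[1] + rate(t),
                k12 * y[0] - k21 * y[1]]

    bps = sorted({0.0, reg.horizon}
                 | {min(e.start, reg.horizon) for e in events}
                 | {min(e.start + e.duration, reg.horizon) for e in events})
    times = np.asarray(times, dtype=float)
    y = np.zeros(2)
    vals = {}
    for a, b in zip(bps, bps[1:]):
        if b - a < 1e-12:
            continue
        sol = solve_ivp(rhs, (a, b), y, method="LSODA",
                        rtol=1e-11, atol=1e-12, dense_output=True)
        for x in times:
            if a <= x <= b:
                vals[float(x)] = sol.sol(x)[0] / ind.v1
        y = sol.y[:, -1]
    return np.array([vals[float(x)] for x in times])
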