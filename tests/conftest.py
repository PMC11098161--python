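"""Shared fixtures: an independent ODE oracle and reusable simulated cohorts."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from pkadherence import get_preset, get_strategy, simulate_strategy


def ode_profile(model, params, doses, times):
    """Reference concentration profile by direct ODE integration.

    Independent of the package's closed-form/eigendecomposition solvers:
    builds the depot + disposition mass-balance equations explicitly and
    integrates piecewise between dose events with a stiff-capable solver.
    """
    p = {name: float(getattr(model, name)) for name in model.structural_params}
    if params:
        p.update({k: float(v) for k, v in params.items()})
    k = model.n_compartments

    def rhs(_t, y):
        dy = np.zeros_like(y)
        dy[0] = -p["ka"] * y[0]
        dy[1] = p["ka"] * y[0] - p["CL"] / p["Vc"] * y[1]
        for i, (q, vp) in enumerate((("Q1", "Vp1"), ("Q2", "Vp2"))[: k - 1], start=2):
            flow = p[q] * (y[1] / p["Vc"] - y[i] / p[vp])
            dy[1] -= flow
            dy[i] += flow
        return dy

    times = np.asarray(times, dtype=float)
    events = sorted((d for d in doses if d.taken), key=lambda d: d.time)
    breakpoints = [d.time for d in events] + [times[-1] + 1.0]
    out = np.zeros_like(times)
    y = np.zeros(k + 1)
    t_now = 0.0
    for d, t_end in zip(events, breakpoints[1:]):
        y[0] += p["F"] * d.f_multiplier * d.amount
        t_stop = min(t_end, times[-1])
        if t_stop <= d.time:
            continue
        mask = (times > d.time) & (times <= t_stop)
        sol = solve_ivp(rhs, (d.time, t_stop), y, t_eval=times[mask],
                        rtol=1e-10, atol=1e-12, method="LSODA", dense_output=False)
        out[mask] = sol.y[1] / p["Vc"]
        y = solve_ivp(rhs, (d.time, t_stop), y, rtol=1e-10, atol=1e-12,
                      method="LSODA").y[:, -1]
        t_now = t_stop
    return out


@pytest.fixture(scope="session")
def ode_oracle():
    return ode_profile


# seed fixed once for the whole suite; cohorts are shared across tests
SUITE_SEED = 20240101


@pytest.fixture(scope="session")
def base_cohorts():
    """2000-individual cohorts per scenario, base model, all strategies."""
    model = get_preset("one_cmt")
    return {
        name: simulate_strategy(model, get_strategy(name), n=2000, seed=SUITE_SEED)
        for name in ("non_dot", "dot_one_dose", "dot_two_dose")
    }


@pytest.fixture(scope="session")
def iiv_cohorts():
    """DOT one-dose cohorts at the three investigated IIV levels."""
    strategy = get_strategy("dot_one_dose")
    return {
        cv: simulate_strategy(get_preset("one_cmt", iiv_cv=cv), strategy,
                              n=2000, seed=SUITE_SEED + 1)
        for cv in (20, 40, 60)
    }
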