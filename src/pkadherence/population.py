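"""Virtual cohorts: between-subject variability, residual error, censoring.

Individual parameters are drawn lognormally around the typical values,
P_i = P * exp(eta_i) with eta_i ~ N(0, omega^2) and omega = CV/100, drawn
independently per parameter and individual.  Observed concentrations carry
proportional residual error, c_obs = c_true * (1 + eps) with
eps ~ N(0, sigma^2), truncated at zero.  An optional lower limit of
quantification (LOQ) marks observations as censored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .pk import PKModel, concentration_profile
from .scenarios import AdherenceScenario

__all__ = [
    "CohortSample",
    "sample_individuals",
    "simulate_cohort",
    "censored_fraction",
    "default_grid",
]

#: default simulation horizon after the scheduled last dose, in multiples
#: of the terminal half-life of the ~24 h base drug (3 half-lives = 72 h)
DEFAULT_HORIZON_H = 72.0
DEFAULT_GRID_STEP_H = 1.0


@dataclass
class CohortSample:
    """Simulated cohort of one adherence scenario.

    ``times`` are hours after the scheduled first dose; ``last_dose_time``
    is the *scheduled* time of the final dose, whether or not that dose was
    taken in this scenario, so that sampling times expressed as
    "h after the last dose" are comparable across scenarios.
    """

    scenario: AdherenceScenario
    params: pd.DataFrame
    times: np.ndarray
    last_dose_time: float
    c_true: np.ndarray  # (n, T), mg/L
    c_obs: np.ndarray  # (n, T), mg/L
    seed: int | None = None
    loq: float | None = None
    below_loq: np.ndarray | None = None  # (n, T) bool, present iff loq set

    def __post_init__(self) -> None:
        n, t = self.c_true.shape
        if self.c_obs.shape != (n, t) or self.times.shape != (t,):
            raise ValueError("inconsistent cohort dimensions")
        if len(self.params) != n:
            raise ValueError("params rows must match number of individuals")
        if np.any(self.c_true < 0):
            raise ValueError("c_true must be nonnegative")

    @property
    def n(self) -> int:
        return self.c_true.shape[0]

    @property
    def times_after_last_dose(self) -> np.ndarray:
        return self.times - self.last_dose_time

    def _time_index(self, hours_after_last_dose: float) -> int:
        target = self.last_dose_time + hours_after_last_dose
        idx = np.argmin(np.abs(self.times - target))
        if not np.isclose(self.times[idx], target, atol=1e-9):
            raise ValueError(
                f"time {hours_after_last_dose} h after last dose is not on the grid"
            )
        return int(idx)

    def observed_at(self, hours_after_last_dose: float) -> np.ndarray:
        """Observed concentrations (mg/L) at one grid time after the
        scheduled last dose."""
        return self.c_obs[:, self._time_index(hours_after_last_dose)]

    def true_at(self, hours_after_last_dose: float) -> np.ndarray:
        return self.c_true[:, self._time_index(hours_after_last_dose)]

    def to_frame(self) -> pd.DataFrame:
        """Long-format export (individual, scenario, time, c_true, c_obs,
        below_loq)."""
        n, t = self.c_true.shape
        frame = pd.DataFrame(
            {
                "individual": np.repeat(np.arange(n), t),
                "scenario": self.scenario.scenario_id,
                "time_h": np.tile(self.times, n),
                "time_after_last_dose_h": np.tile(self.times_after_last_dose, n),
                "c_true_mg_l": self.c_true.ravel(),
                "c_obs_mg_l": self.c_obs.ravel(),
            }
        )
        frame["below_loq"] = (
            self.below_loq.ravel() if self.below_loq is not None else False
        )
        return frame


def sample_individuals(
    model: PKModel, n: int, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Draw n individual parameter sets with lognormal between-subject
    variability; a CV of zero leaves a parameter at its typical value."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    columns = {}
    for name in model.structural_params:
        typical = float(getattr(model, name))
        omega = model.iiv_cv.get(name, 0.0) / 100.0
        eta = rng.normal(0.0, omega, size=n)
        columns[name] = typical * np.exp(eta)
    return pd.DataFrame(columns)


def default_grid(last_dose_time: float, horizon: float = DEFAULT_HORIZON_H,
                 step: float = DEFAULT_GRID_STEP_H) -> np.ndarray:
    """Hourly grid from the first dose to ``horizon`` h past the scheduled
    last dose."""
    return np.arange(0.0, last_dose_time + horizon + step / 2, step)


def simulate_cohort(
    model: PKModel,
    scenario: AdherenceScenario,
    n: int = 2000,
    times: Sequence[float] | None = None,
    seed: int | np.random.Generator | None = None,
    loq: float | None = None,
    last_dose_time: float | None = None,
) -> CohortSample:
    """Simulate a cohort under one adherence scenario.

    Each individual gets lognormally varied parameters, a noise-free
    profile by superposition over the taken doses, and proportional
    residual error on every grid point.  Identical seeds give bit-identical
    cohorts.
    """
    if seed is None:
        raise ValueError("a seed is required for stochastic simulation")
    rng = np.random.default_rng(seed)
    if last_dose_time is None:
        last_dose_time = max(d.time for d in scenario.doses)
    times_arr = (
        default_grid(last_dose_time) if times is None else np.asarray(times, dtype=float)
    )
    params = sample_individuals(model, n, rng)
    c_true = concentration_profile(
        model, {k: params[k].to_numpy() for k in params.columns}, scenario.doses, times_arr
    )
    eps = rng.normal(0.0, np.sqrt(model.ruv_var), size=c_true.shape)
    c_obs = np.clip(c_true * (1.0 + eps), 0.0, None)
    below = (c_obs < loq) if loq is not None else None
    return CohortSample(
        scenario=scenario,
        params=params,
        times=times_arr,
        last_dose_time=float(last_dose_time),
        c_true=c_true,
        c_obs=c_obs,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        loq=loq,
        below_loq=below,
    )


def censored_fraction(sample: CohortSample, hours_after_last_dose: float) -> float:
    """Fraction of individuals whose observation at the given time falls
    below the LOQ."""
    if sample.below_loq is None:
        raise ValueError("cohort was simulated without an LOQ")
    idx = sample._time_index(hours_after_last_dose)
    return float(np.mean(sample.below_loq[:, idx]))
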