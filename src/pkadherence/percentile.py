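"""The percentile method for adherence classification.

A concentration cutoff is the empirical percentile of the simulated
full-adherence concentration distribution at the sampling time; a measured
concentration strictly below the cutoff is called poor adherence.  The
cutoff percentile is tuned over a 5-95% grid (5%-unit steps) by maximising
Youden's index against the pooled poor-adherence scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CutoffResult",
    "derive_cutoff",
    "classify",
    "is_poor",
    "percentile_profile",
    "optimal_percentile",
    "DEFAULT_GRID",
]

#: cutoff percentiles investigated when searching for the optimum
DEFAULT_GRID: tuple[float, ...] = tuple(range(5, 100, 5))


@dataclass(frozen=True)
class CutoffResult:
    """A derived concentration cutoff.

    ``cutoff`` is in the same units as the input concentrations (mg/L for
    cohorts simulated by this package; multiply by 1000 for ng/mL).
    """

    percentile: float
    cutoff: float
    time: float | None = None  # sampling time, h after scheduled last dose
    n_reference: int = 0


def derive_cutoff(
    full_adherence_concs: Sequence[float],
    percentile: float,
    time: float | None = None,
) -> CutoffResult:
    """Empirical percentile cutoff from a full-adherence reference cohort.

    Uses linear interpolation between order statistics, so that for a
    reference cohort of n the number of reference individuals strictly
    below the cutoff is exactly round(percentile/100 * n) for percentiles
    on a 5%-grid with n a multiple of 20.
    """
    concs = np.asarray(full_adherence_concs, dtype=float)
    concs = concs[np.isfinite(concs)]
    if concs.size < 2:
        raise ValueError("need at least 2 finite reference concentrations")
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    cutoff = float(np.quantile(concs, percentile / 100.0))
    return CutoffResult(
        percentile=float(percentile), cutoff=cutoff, time=time, n_reference=concs.size
    )


def is_poor(concs, cutoff: CutoffResult | float) -> np.ndarray:
    """Vectorised classification: True where a concentration is strictly
    below the cutoff (ties count as full adherence)."""
    c = cutoff.cutoff if isinstance(cutoff, CutoffResult) else float(cutoff)
    return np.asarray(concs, dtype=float) < c


def classify(conc: float, cutoff: CutoffResult) -> str:
    """Binary adherence call for one measured concentration."""
    if not np.isfinite(conc) or conc < 0:
        raise ValueError("concentration must be finite and >= 0")
    return "poor" if conc < cutoff.cutoff else "full"


def percentile_profile(
    full_concs: Sequence[float],
    poor_concs: Sequence[Sequence[float]],
    grid: Sequence[float] = DEFAULT_GRID,
    time: float | None = None,
) -> pd.DataFrame:
    """Sensitivity/specificity/Youden profile over a cutoff-percentile grid.

    Specificity is evaluated on the cutoff-derivation (full-adherence)
    cohort itself, so it equals 1 - percentile/100 up to 1/n; sensitivity
    pools the poor-adherence cohorts with equal weight (equiprobable
    scenario prevalence).
    """
    full = np.asarray(full_concs, dtype=float)
    pooled_poor = np.concatenate([np.asarray(c, dtype=float) for c in poor_concs])
    rows = []
    for p in grid:
        cut = derive_cutoff(full, p, time=time)
        spec = float(np.mean(~is_poor(full, cut)))
        sens = float(np.mean(is_poor(pooled_poor, cut)))
        rows.append(
            {
                "percentile": float(p),
                "cutoff": cut.cutoff,
                "sensitivity": sens,
                "specificity": spec,
                "youden": sens + spec - 1.0,
            }
        )
    return pd.DataFrame(rows)


def optimal_percentile(
    full_concs: Sequence[float],
    poor_concs: Sequence[Sequence[float]],
    grid: Sequence[float] = DEFAULT_GRID,
    time: float | None = None,
) -> tuple[CutoffResult, pd.DataFrame]:
    """Grid percentile maximising Youden's index.

    Ties are broken toward the lower percentile (higher specificity).
    Returns the winning cutoff plus the full profile table.
    """
    profile = percentile_profile(full_concs, poor_concs, grid=grid, time=time)
    best = int(np.argmax(profile["youden"].to_numpy()))  # first max = lowest percentile
    row = profile.iloc[best]
    cut = CutoffResult(
        percentile=float(row["percentile"]),
        cutoff=float(row["cutoff"]),
        time=time,
        n_reference=len(np.asarray(full_concs)),
    )
    return cut, profile
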