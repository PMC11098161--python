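"""Predictive-performance metrics and sensitivity-analysis drivers.

Sensitivity is the fraction of truly poor-adherent individuals called poor;
specificity the fraction of truly full-adherent individuals called full.
Youden's index J = sensitivity + specificity - 1 summarises one operating
point; the ROC curve (sensitivity vs 1 - specificity over the cutoff grid)
with trapezoidal AUC summarises the whole cutoff family.

Poor-adherence scenarios are pooled with equal weight (equiprobable
scenario prevalence, equal cohort sizes); specificity is evaluated on the
full-adherence cohort that also served to derive the percentile cutoffs,
so ROC x-coordinates equal percentile/100 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import bayes as bayes_mod
from . import percentile as pct
from .pk import PKModel
from .population import CohortSample, simulate_cohort
from .scenarios import DosingStrategy, enumerate_scenarios

__all__ = [
    "ConfusionTable",
    "ROCResult",
    "confusion",
    "youden",
    "roc",
    "simulate_strategy",
    "StrategyCohorts",
    "percentile_performance",
    "bayes_performance",
    "sweep_sampling_times",
    "loq_sweep",
    "ROC_GRID",
]

#: percentile grid used for ROC construction: the 5%-unit search grid plus
#: the 0 and 100 anchors
ROC_GRID: tuple[float, ...] = tuple(range(0, 101, 5))


@dataclass(frozen=True)
class ConfusionTable:
    """Two-by-two adherence classification table.

    tp/fn count truly poor-adherent individuals (called poor / called
    full); tn/fp count truly full-adherent individuals (called full /
    called poor).
    """

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def sensitivity(self) -> float | None:
        total = self.tp + self.fn
        return self.tp / total if total else None

    @property
    def specificity(self) -> float | None:
        total = self.tn + self.fp
        return self.tn / total if total else None

    @property
    def youden(self) -> float | None:
        if self.sensitivity is None or self.specificity is None:
            return None
        return self.sensitivity + self.specificity - 1.0


def confusion(pred_poor, truth_poor) -> ConfusionTable:
    """Build the two-by-two table from boolean arrays (True = poor)."""
    pred = np.asarray(pred_poor, dtype=bool)
    truth = np.asarray(truth_poor, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("predictions and truth must have equal length")
    return ConfusionTable(
        tp=int(np.sum(pred & truth)),
        fn=int(np.sum(~pred & truth)),
        tn=int(np.sum(~pred & ~truth)),
        fp=int(np.sum(pred & ~truth)),
    )


def youden(sensitivity: float, specificity: float) -> float:
    """J = sensitivity + specificity - 1."""
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("sensitivity and specificity must be in [0, 1]")
    return sensitivity + specificity - 1.0


@dataclass(frozen=True)
class ROCResult:
    """ROC points (1-specificity, sensitivity) and trapezoidal AUC."""

    points: np.ndarray  # (m, 2), sorted by x, includes (0,0) and (1,1)
    auc: float
    time: float | None = None
    strategy: str | None = None

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.points, columns=["one_minus_specificity", "sensitivity"])
        frame["auc"] = self.auc
        return frame


def _roc_from_points(xs, ys, time=None, strategy=None) -> ROCResult:
    pts = np.column_stack([xs, ys])
    pts = np.vstack([pts, [0.0, 0.0], [1.0, 1.0]])
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return ROCResult(points=pts, auc=auc, time=time, strategy=strategy)


def roc(
    full_concs: Sequence[float],
    poor_concs: Sequence[Sequence[float]],
    grid: Sequence[float] = ROC_GRID,
    time: float | None = None,
    strategy: str | None = None,
) -> ROCResult:
    """Percentile-method ROC curve over a cutoff-percentile grid.

    One operating point per grid percentile; the degenerate 0 and 100
    entries anchor at the cohort minimum/maximum, and the (0,0)/(1,1)
    corners are always appended before the trapezoidal AUC.
    """
    full = np.asarray(full_concs, dtype=float)
    pooled = np.concatenate([np.asarray(c, dtype=float) for c in poor_concs])
    xs, ys = [], []
    for p in grid:
        cut = float(np.quantile(full, min(max(p, 0.0), 100.0) / 100.0))
        xs.append(float(np.mean(full < cut)))
        ys.append(float(np.mean(pooled < cut)))
    return _roc_from_points(xs, ys, time=time, strategy=strategy)


# ---------------------------------------------------------------------------
# simulation drivers


@dataclass
class StrategyCohorts:
    """Simulated cohorts for every scenario of one dosing strategy."""

    strategy: DosingStrategy
    cohorts: list[CohortSample]  # same order as enumerate_scenarios
    seed: int

    @property
    def full(self) -> CohortSample:
        return self.cohorts[0]

    @property
    def poor(self) -> list[CohortSample]:
        return self.cohorts[1:]

    def concs_at(self, hours_after_last_dose: float):
        """(full_concs, [poor_concs...]) observed at one sampling time."""
        return (
            self.full.observed_at(hours_after_last_dose),
            [c.observed_at(hours_after_last_dose) for c in self.poor],
        )


def simulate_strategy(
    model: PKModel,
    strategy: DosingStrategy,
    n: int = 2000,
    seed: int = 0,
    times: Sequence[float] | None = None,
    loq: float | None = None,
    occasion_f_increase: float = 0.0,
    amounts: Sequence[float] | None = None,
) -> StrategyCohorts:
    """Simulate an independent n-individual cohort per adherence scenario.

    The global seed spawns one child seed per scenario (in scenario order)
    so that adding scenarios never perturbs the draws of existing ones.
    All cohorts share the time grid, referenced to the *scheduled* last
    dose.
    """
    scenarios = enumerate_scenarios(
        strategy, occasion_f_increase=occasion_f_increase, amounts=amounts
    )
    children = np.random.SeedSequence(seed).spawn(len(scenarios))
    last = strategy.last_dose_time
    cohorts = [
        simulate_cohort(
            model, sc, n=n, times=times, seed=np.random.default_rng(child),
            loq=loq, last_dose_time=last,
        )
        for sc, child in zip(scenarios, children)
    ]
    return StrategyCohorts(strategy=strategy, cohorts=cohorts, seed=seed)


def percentile_performance(
    cohorts: StrategyCohorts,
    hours_after_last_dose: float,
    grid: Sequence[float] = pct.DEFAULT_GRID,
) -> dict:
    """Best-grid percentile operating point plus ROC AUC at one time."""
    full, poor = cohorts.concs_at(hours_after_last_dose)
    best, profile = pct.optimal_percentile(full, poor, grid=grid,
                                           time=hours_after_last_dose)
    row = profile.loc[profile["percentile"] == best.percentile].iloc[0]
    curve = roc(full, poor, time=hours_after_last_dose,
                strategy=cohorts.strategy.name)
    return {
        "time_after_last_dose_h": float(hours_after_last_dose),
        "method": "percentile",
        "percentile": best.percentile,
        "cutoff_mg_l": best.cutoff,
        "sensitivity": float(row["sensitivity"]),
        "specificity": float(row["specificity"]),
        "youden": float(row["youden"]),
        "auc": curve.auc,
        "profile": profile,
        "roc": curve,
    }


def bayes_performance(
    cohorts: StrategyCohorts, hours_after_last_dose: float
) -> dict:
    """Bayesian-method operating point (single threshold family, no ROC)."""
    scenario_concs = [c.observed_at(hours_after_last_dose) for c in cohorts.cohorts]
    priors = [c.scenario.prior for c in cohorts.cohorts]
    ids = [c.scenario.scenario_id for c in cohorts.cohorts]
    model = bayes_mod.build_bins(scenario_concs, priors, scenario_ids=ids, full_index=0)
    labels_full, _ = bayes_mod.classify_bayes(scenario_concs[0], model)
    spec = float(np.mean(labels_full == "full"))
    pooled = np.concatenate(scenario_concs[1:])
    labels_poor, _ = bayes_mod.classify_bayes(pooled, model)
    sens = float(np.mean(labels_poor == "poor"))
    return {
        "time_after_last_dose_h": float(hours_after_last_dose),
        "method": "bayes",
        "sensitivity": sens,
        "specificity": spec,
        "youden": sens + spec - 1.0,
        "bin_model": model,
    }


def sweep_sampling_times(
    model: PKModel,
    strategy: DosingStrategy,
    times_after_last_dose: Sequence[float] = tuple(range(1, 73)),
    n: int = 2000,
    seed: int = 0,
    methods: Sequence[str] = ("percentile", "bayes"),
    grid: Sequence[float] = pct.DEFAULT_GRID,
    cohorts: StrategyCohorts | None = None,
) -> pd.DataFrame:
    """Youden's index (and, for the percentile method, ROC AUC) as a
    function of sampling time after the scheduled last dose.

    Cohorts are simulated once on the shared hourly grid and re-read at
    every sampling time; pass ``cohorts`` to reuse an existing simulation.
    """
    if cohorts is None:
        cohorts = simulate_strategy(model, strategy, n=n, seed=seed)
    rows = []
    for t in times_after_last_dose:
        if "percentile" in methods:
            perf = percentile_performance(cohorts, t, grid=grid)
            rows.append({k: perf[k] for k in (
                "time_after_last_dose_h", "method", "percentile",
                "sensitivity", "specificity", "youden", "auc")})
        if "bayes" in methods:
            perf = bayes_performance(cohorts, t)
            rows.append({k: perf.get(k) for k in (
                "time_after_last_dose_h", "method", "percentile",
                "sensitivity", "specificity", "youden", "auc")})
    out = pd.DataFrame(rows)
    out.insert(1, "strategy", strategy.name)
    out.insert(0, "time_h", out["time_after_last_dose_h"] + strategy.last_dose_time)
    return out


def loq_sweep(
    model: PKModel,
    strategy: DosingStrategy,
    hours_after_last_dose: float = 24.0,
    censored_fractions: Sequence[float] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
    n: int = 2000,
    seed: int = 0,
    grid: Sequence[float] = pct.DEFAULT_GRID,
    cohorts: StrategyCohorts | None = None,
) -> pd.DataFrame:
    """Impact of assay censoring on the percentile method at one time.

    Each censoring level sets the LOQ at the corresponding empirical
    percentile of the full-adherence observations.  Censored observations
    are replaced by zero (below every admissible cutoff, hence always
    called poor); cutoffs whose percentile concentration falls below the
    LOQ are raised to the LOQ and flagged non-evaluable.
    """
    if cohorts is None:
        cohorts = simulate_strategy(model, strategy, n=n, seed=seed)
    full, poor = cohorts.concs_at(hours_after_last_dose)
    pooled_poor = np.concatenate(poor)
    rows = []
    for frac in censored_fractions:
        loq = float(np.quantile(full, frac)) if frac > 0 else 0.0
        full_c = np.where(full < loq, 0.0, full)
        poor_c = np.where(pooled_poor < loq, 0.0, pooled_poor)
        # ROC over the grid with LOQ-floored cutoffs
        xs, ys, table = [], [], []
        for p in ROC_GRID:
            raw = float(np.quantile(full_c, p / 100.0))
            cut = max(raw, loq)
            spec = float(np.mean(full_c >= cut))
            sens = float(np.mean(poor_c < cut))
            xs.append(1.0 - spec)
            ys.append(sens)
            if p in grid:
                table.append((p, cut, sens, spec, sens + spec - 1.0, raw < loq))
        curve = _roc_from_points(xs, ys, time=hours_after_last_dose,
                                 strategy=cohorts.strategy.name)
        tbl = pd.DataFrame(
            table,
            columns=["percentile", "cutoff", "sensitivity", "specificity",
                     "youden", "cutoff_at_loq"],
        )
        best = tbl.iloc[int(np.argmax(tbl["youden"].to_numpy()))]
        rows.append(
            {
                "censored_fraction": float(frac),
                "loq_mg_l": loq,
                "auc": curve.auc,
                "optimal_percentile": float(best["percentile"]),
                "youden": float(best["youden"]),
                "sensitivity": float(best["sensitivity"]),
                "specificity": float(best["specificity"]),
            }
        )
    return pd.DataFrame(rows)
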