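"""Run configuration: YAML loading, validation, defaults.

A run configuration names (or inlines) a PK model and dosing strategy,
fixes the cohort size and seed, and selects sampling times, methods and
cutoff-percentile grid.  The seed is mandatory for any stochastic run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .pk import PKModel, PRESETS, get_preset
from .scenarios import DosingStrategy, STRATEGIES, get_strategy

__all__ = ["RunConfig", "load_config", "model_from_spec", "strategy_from_spec"]

_MODEL_KEYS = {"preset", "iiv_cv", "n_compartments", "ka", "F", "CL", "Vc",
               "Q1", "Vp1", "Q2", "Vp2", "ruv_var"}


@dataclass
class RunConfig:
    model: PKModel
    strategy: DosingStrategy
    seed: int
    n_individuals: int = 2000
    times_after_last_dose: tuple[float, ...] = (24.0,)
    methods: tuple[str, ...] = ("percentile",)
    percentile_grid: tuple[float, ...] = tuple(range(5, 100, 5))
    loq: float | None = None
    output: str | None = None

    def digest(self) -> str:
        """Short stable hash of the configuration, for run logging."""
        payload = {
            "model": self.model.typical_values()
            | {"iiv_cv": dict(self.model.iiv_cv), "ruv_var": self.model.ruv_var},
            "strategy": [self.strategy.n_doses, self.strategy.interval,
                         self.strategy.amount, self.strategy.n_observed],
            "seed": self.seed,
            "n": self.n_individuals,
            "times": list(self.times_after_last_dose),
            "methods": list(self.methods),
            "grid": list(self.percentile_grid),
            "loq": self.loq,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


class ConfigError(ValueError):
    """Configuration problem, reported with the offending field path."""


def model_from_spec(spec, path: str = "model") -> PKModel:
    """Build a PKModel from a preset name or an inline parameter mapping."""
    if isinstance(spec, str):
        try:
            return get_preset(spec)
        except KeyError:
            raise ConfigError(
                f"{path}: unknown preset {spec!r}; available presets: "
                + ", ".join(sorted(PRESETS))
            ) from None
    if not isinstance(spec, dict):
        raise ConfigError(f"{path}: expected a preset name or a mapping")
    unknown = set(spec) - _MODEL_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    if "preset" in spec:
        model = model_from_spec(spec["preset"], path=f"{path}.preset")
        if "iiv_cv" in spec:
            model = model.with_iiv(spec["iiv_cv"])
        return model
    try:
        kwargs = {k: v for k, v in spec.items() if k != "iiv_cv"}
        model = PKModel(**kwargs)
        if "iiv_cv" in spec:
            model = model.with_iiv(spec["iiv_cv"])
        return model
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from None


def strategy_from_spec(spec, path: str = "strategy") -> DosingStrategy:
    if isinstance(spec, str):
        try:
            return get_strategy(spec)
        except KeyError:
            raise ConfigError(
                f"{path}: unknown strategy {spec!r}; available: "
                + ", ".join(sorted(STRATEGIES))
            ) from None
    if not isinstance(spec, dict):
        raise ConfigError(f"{path}: expected a strategy name or a mapping")
    try:
        return DosingStrategy(**spec)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from None


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Required keys: ``model``, ``strategy``, ``seed``.  Defaults:
    n_individuals 2000, sampling time 24 h after the scheduled last dose,
    percentile method, 5-95% grid in 5% steps.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    for key in ("model", "strategy"):
        if key not in raw:
            raise ConfigError(f"{key}: required key missing")
    if "seed" not in raw:
        raise ConfigError("seed: required for stochastic runs")
    if not isinstance(raw["seed"], int):
        raise ConfigError("seed: must be an integer")
    model = model_from_spec(raw["model"])
    strategy = strategy_from_spec(raw["strategy"])
    n = raw.get("n_individuals", 2000)
    if not isinstance(n, int) or n < 1:
        raise ConfigError("n_individuals: must be a positive integer")
    times = raw.get("times_after_last_dose", [24.0])
    if not isinstance(times, (list, tuple)) or not times:
        raise ConfigError("times_after_last_dose: must be a non-empty list")
    methods = tuple(raw.get("methods", ["percentile"]))
    for m in methods:
        if m not in ("percentile", "bayes"):
            raise ConfigError(f"methods: unknown method {m!r}")
    grid = tuple(raw.get("percentile_grid", range(5, 100, 5)))
    loq = raw.get("loq")
    if loq is not None and (not isinstance(loq, (int, float)) or loq < 0):
        raise ConfigError("loq: must be a nonnegative number")
    return RunConfig(
        model=model,
        strategy=strategy,
        seed=raw["seed"],
        n_individuals=n,
        times_after_last_dose=tuple(float(t) for t in times),
        methods=methods,
        percentile_grid=grid,
        loq=loq,
        output=raw.get("output"),
    )
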