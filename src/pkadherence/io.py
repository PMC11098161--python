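"""Tabular report writing and small deterministic test fixtures."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import ConfusionTable, ROCResult, simulate_strategy
from .pk import PRESETS
from .scenarios import STRATEGIES

__all__ = [
    "write_confusion",
    "write_roc",
    "write_table",
    "generate_fixtures",
]

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.12g"  # round-trips float64 to ~1e-12 relative


def write_confusion(table: ConfusionTable, path: str | Path) -> Path:
    """Write a two-by-two table with its derived rates as one CSV row."""
    path = Path(path)
    frame = pd.DataFrame(
        [{
            "tp": table.tp, "fn": table.fn, "tn": table.tn, "fp": table.fp,
            "sensitivity": table.sensitivity, "specificity": table.specificity,
        }]
    )
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def write_roc(result: ROCResult, path: str | Path) -> Path:
    path = Path(path)
    result.to_frame().to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def write_table(frame: pd.DataFrame, path: str | Path) -> Path:
    """Generic CSV report with a fixed column order and lossless floats."""
    path = Path(path)
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    logger.info("wrote %s (%d rows)", path, len(frame))
    return path


def generate_fixtures(seed: int, outdir: str | Path, n: int = 200) -> list[Path]:
    """Small deterministic cohorts (one CSV per preset x strategy) for fast
    regression tests; identical seeds reproduce identical files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for mi, model_name in enumerate(sorted(PRESETS)):
        for si, strat_name in enumerate(sorted(STRATEGIES)):
            child = int(
                np.random.SeedSequence([seed, mi, si]).generate_state(1)[0] % 2**31
            )
            cohorts = simulate_strategy(
                PRESETS[model_name], STRATEGIES[strat_name], n=n, seed=child,
                times=np.arange(0.0, 121.0, 12.0),
            )
            frame = pd.concat([c.to_frame() for c in cohorts.cohorts], ignore_index=True)
            path = outdir / f"cohort_{model_name}_{strat_name}.csv"
            frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)
            written.append(path)
    logger.info("wrote %d fixture files under %s (seed %d)", len(written), outdir, seed)
    return written
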