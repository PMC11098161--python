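"""The Bayesian method for adherence classification.

Concentrations from all adherence scenarios at the sampling time are pooled
and cut into 20 bins at the pooled 5,10,...,95 percentiles.  Each scenario's
conditional probability vector is its fraction of concentrations per bin.
For a measured concentration C in bin b,

    P(scenario_j | C) = P(scenario_j) * p(b | scenario_j) / p(b),
    p(b) = sum_k P(scenario_k) * p(b | scenario_k),

with equiprobable priors by default.  The adherence call is the argmax
scenario; the call is "full" exactly when that scenario is full adherence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["BinModel", "build_bins", "posterior", "classify_bayes"]

logger = logging.getLogger(__name__)

N_BINS = 20


@dataclass(frozen=True)
class BinModel:
    """Pooled-percentile bins plus per-scenario conditional probabilities.

    ``edges`` are the 19 interior boundaries; bin membership is half-open,
    [edge_b, edge_{b+1}), with a value exactly on an edge belonging to the
    upper bin and the extreme bins open-ended.
    """

    edges: np.ndarray  # (19,)
    conditionals: np.ndarray  # (n_scenarios, 20), rows sum to 1
    priors: np.ndarray  # (n_scenarios,), sums to 1
    scenario_ids: tuple[str, ...]
    full_index: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if np.any(np.diff(self.edges) < 0):
            raise ValueError("bin edges must be nondecreasing")
        if not np.allclose(self.conditionals.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("each conditional vector must sum to 1")
        if not np.isclose(self.priors.sum(), 1.0, atol=1e-12):
            raise ValueError("priors must sum to 1")

    @property
    def n_scenarios(self) -> int:
        return self.conditionals.shape[0]

    def bin_of(self, concs) -> np.ndarray:
        """Bin index (0..19) of each concentration."""
        return np.searchsorted(self.edges, np.asarray(concs, dtype=float), side="right")

    def to_frame(self) -> pd.DataFrame:
        """Scenario-by-bin conditional matrix for export."""
        frame = pd.DataFrame(
            self.conditionals,
            index=pd.Index(self.scenario_ids, name="scenario"),
            columns=[f"bin_{b:02d}" for b in range(N_BINS)],
        )
        frame.insert(0, "prior", self.priors)
        return frame


def build_bins(
    scenario_concs: Sequence[Sequence[float]],
    priors: Sequence[float],
    scenario_ids: Sequence[str] | None = None,
    full_index: int = 0,
) -> BinModel:
    """Build the bin model from per-scenario concentration samples.

    The pooled set (all scenarios concatenated) defines the 5%-unit
    percentile edges; conditionals count each scenario's mass per bin.
    A degenerate pooled distribution (all values equal) collapses to a
    single informative bin and is flagged.
    """
    samples = [np.asarray(c, dtype=float) for c in scenario_concs]
    if any(s.size == 0 for s in samples):
        raise ValueError("every scenario must contribute at least one concentration")
    priors_arr = np.asarray(priors, dtype=float)
    if priors_arr.shape != (len(samples),):
        raise ValueError("one prior per scenario required")
    if not np.isclose(priors_arr.sum(), 1.0):
        raise ValueError("priors must sum to 1")
    pooled = np.concatenate(samples)
    edges = np.quantile(pooled, np.arange(5, 100, 5) / 100.0)
    degenerate = bool(np.isclose(edges[0], edges[-1]))
    if degenerate:
        logger.warning(
            "degenerate pooled concentration distribution: all percentile "
            "edges coincide; bin model carries a single informative bin"
        )
    conditionals = np.empty((len(samples), N_BINS))
    for j, s in enumerate(samples):
        idx = np.searchsorted(edges, s, side="right")
        conditionals[j] = np.bincount(idx, minlength=N_BINS) / s.size
    ids = tuple(scenario_ids) if scenario_ids is not None else tuple(
        f"scenario_{j}" for j in range(len(samples))
    )
    return BinModel(
        edges=edges,
        conditionals=conditionals,
        priors=priors_arr,
        scenario_ids=ids,
        full_index=full_index,
        degenerate=degenerate,
    )


def posterior(conc, model: BinModel) -> np.ndarray:
    """Posterior scenario probabilities for one or more concentrations.

    Returns shape (n_scenarios,) for a scalar or (m, n_scenarios) for an
    array.  If the bin containing a concentration is empty under every
    scenario the prior vector is returned for it (and a warning logged).
    """
    concs = np.asarray(conc, dtype=float)
    scalar = concs.ndim == 0
    bins = model.bin_of(np.atleast_1d(concs))
    lik = model.conditionals[:, bins].T  # (m, n_scenarios)
    joint = lik * model.priors
    denom = joint.sum(axis=1, keepdims=True)
    empty = denom[:, 0] == 0.0
    if empty.any():
        logger.warning(
            "%d concentration(s) fell in a bin with zero mass under every "
            "scenario; returning the prior", int(empty.sum()),
        )
        joint[empty] = model.priors
        denom = joint.sum(axis=1, keepdims=True)
    post = joint / denom
    return post[0] if scalar else post


def classify_bayes(conc, model: BinModel):
    """Adherence call from the most plausible scenario.

    The most plausible scenario is the posterior argmax; exact ties go to
    the full-adherence scenario if it participates in the tie, else to the
    lowest scenario index.  The binary call is "full" iff the winner is the
    full-adherence scenario.

    Returns ``(label, scenario_index)`` for a scalar concentration, or
    ``(labels, scenario_indices)`` arrays for array input.
    """
    concs = np.asarray(conc, dtype=float)
    scalar = concs.ndim == 0
    post = np.atleast_2d(posterior(concs, model))
    maxval = post.max(axis=1, keepdims=True)
    tied = np.isclose(post, maxval, rtol=0.0, atol=0.0)
    winner = np.argmax(tied, axis=1)  # lowest tied index
    full_tied = tied[:, model.full_index]
    winner = np.where(full_tied, model.full_index, winner)
    labels = np.where(winner == model.full_index, "full", "poor")
    if scalar:
        return str(labels[0]), int(winner[0])
    return labels, winner
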