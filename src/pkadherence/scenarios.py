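"""Adherence scenarios: which scheduled doses were actually taken.

A regimen with k unobserved doses has 2^k possible dose-taking patterns
("scenarios").  Doses given under directly observed therapy (DOT) are known
to be taken, so only the unobserved tail generates adherence uncertainty.
Full adherence means every scheduled dose was taken; missing at least one
dose is poor adherence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .pk import DoseEvent

__all__ = [
    "DosingStrategy",
    "AdherenceScenario",
    "enumerate_scenarios",
    "assign_priors",
    "get_strategy",
    "STRATEGIES",
]

FULL = "full"
POOR = "poor"


@dataclass(frozen=True)
class DosingStrategy:
    """A scheduled multi-dose regimen plus its level of observation.

    ``n_observed`` initial doses are administered under direct observation
    and therefore known to be taken; adherence to the remaining
    ``n_doses - n_observed`` doses is what the framework assesses.
    """

    n_doses: int
    interval: float  # h between scheduled doses
    amount: float  # mg per dose
    n_observed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if self.n_doses < 1:
            raise ValueError("n_doses must be >= 1")
        if self.interval <= 0:
            raise ValueError("interval must be > 0")
        if self.amount <= 0:
            raise ValueError("amount must be > 0")
        if not 0 <= self.n_observed <= self.n_doses:
            raise ValueError("n_observed must be between 0 and n_doses")

    @property
    def dose_times(self) -> tuple[float, ...]:
        return tuple(i * self.interval for i in range(self.n_doses))

    @property
    def last_dose_time(self) -> float:
        """Scheduled time of the final dose (h after the first dose)."""
        return (self.n_doses - 1) * self.interval

    @property
    def n_unobserved(self) -> int:
        return self.n_doses - self.n_observed


@dataclass(frozen=True)
class AdherenceScenario:
    """One dose-taking pattern with its label and prior probability."""

    taken: tuple[bool, ...]
    label: str  # FULL or POOR
    doses: tuple[DoseEvent, ...]
    prior: float | None = None
    scenario_id: str = ""

    @property
    def is_full(self) -> bool:
        return self.label == FULL


#: The three dosing strategies of the illustrative 3-day once-daily 200 mg
#: regimen: no observation (8 scenarios), first dose observed (4), first
#: two doses observed (2).
STRATEGIES: dict[str, DosingStrategy] = {
    "non_dot": DosingStrategy(3, 24.0, 200.0, 0, name="non_dot"),
    "dot_one_dose": DosingStrategy(3, 24.0, 200.0, 1, name="dot_one_dose"),
    "dot_two_dose": DosingStrategy(3, 24.0, 200.0, 2, name="dot_two_dose"),
}


def get_strategy(name: str) -> DosingStrategy:
    try:
        return STRATEGIES[name]
    except KeyError:
        raise KeyError(
            f"unknown strategy {name!r}; available: {', '.join(sorted(STRATEGIES))}"
        ) from None


def enumerate_scenarios(
    strategy: DosingStrategy,
    occasion_f_increase: float = 0.0,
    amounts: Sequence[float] | None = None,
) -> list[AdherenceScenario]:
    """All 2^(n_doses - n_observed) dose-taking patterns of a strategy.

    Ordered deterministically with full adherence first, then by the binary
    pattern of missed unobserved doses (earliest dose = most significant
    bit).  Observed doses are always taken.

    ``occasion_f_increase`` applies a compounding relative-bioavailability
    increase per dosing occasion (dose i gets (1+inc)^i); ``amounts``
    optionally overrides the per-dose amount (e.g. weight-band dosing).
    """
    k = strategy.n_unobserved
    if amounts is None:
        amounts = [strategy.amount] * strategy.n_doses
    elif len(amounts) != strategy.n_doses:
        raise ValueError("amounts must have one entry per scheduled dose")
    scenarios = []
    for pattern in range(2**k):
        taken = [True] * strategy.n_observed
        for bit in range(k):
            missed = bool((pattern >> (k - 1 - bit)) & 1)
            taken.append(not missed)
        doses = tuple(
            DoseEvent(
                time=i * strategy.interval,
                amount=amounts[i],
                taken=taken[i],
                f_multiplier=(1.0 + occasion_f_increase) ** i,
            )
            for i in range(strategy.n_doses)
        )
        label = FULL if all(taken) else POOR
        sid = "".join("T" if t else "X" for t in taken)
        scenarios.append(
            AdherenceScenario(taken=tuple(taken), label=label, doses=doses, scenario_id=sid)
        )
    return assign_priors(scenarios)


def assign_priors(
    scenarios: list[AdherenceScenario], mode: str = "equiprobable"
) -> list[AdherenceScenario]:
    """Attach prior probabilities; ``equiprobable`` gives each scenario
    1/len(scenarios) (0.125, 0.25, 0.5 for the 8/4/2-scenario strategies)."""
    if not scenarios:
        raise ValueError("no scenarios")
    if mode != "equiprobable":
        raise ValueError(f"unknown prior mode {mode!r}")
    prior = 1.0 / len(scenarios)
    return [replace(s, prior=prior) for s in scenarios]
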