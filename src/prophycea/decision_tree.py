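"""Initial 100-day decision tree.

Each prophylaxis strategy carries a per-day drug cost and a duration
(blended across agents for the first-generation comparator, where 81% of
patients receive fluconazole and the rest itraconazole).  Over the first
100 days a patient either develops an invasive fungal infection (IFI) or
not, and either dies — of the IFI or of other causes — or survives.  The
tree yields the four terminal-state probabilities, the expected
prophylaxis and IFI-management costs, and the life-years/QALYs accrued
during the initial period.  Costs are never discounted (they all fall in
the first 100 days).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .parameters import ModelSettings

__all__ = [
    "Component",
    "Strategy",
    "TreeOutcome",
    "builtin_strategies",
    "prophylaxis_cost",
    "evaluate_tree",
]

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class Component:
    """One drug in a regimen: draw keys for its daily cost and duration."""

    cost: str
    duration: str
    weight: float


@dataclass(frozen=True)
class Strategy:
    name: str
    components: tuple[Component, ...]
    p_ifi_parameter: str

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError(f"{self.name}: strategy needs >= 1 component")
        total = sum(c.weight for c in self.components)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"{self.name}: component weights sum to {total}, not 1")
        if any(c.weight < 0 for c in self.components):
            raise ValueError(f"{self.name}: negative component weight")


def builtin_strategies(settings: ModelSettings) -> dict[str, Strategy]:
    """The three published regimens.

    The first-generation comparator blends fluconazole (400 mg qd, 24 d)
    and itraconazole (200 mg bid, 29 d) at the fluconazole share from the
    settings; both posaconazole formulations share the same IFI
    probability (equal prophylactic efficacy assumed).
    """
    w = settings.fluconazole_share
    return {
        "posaconazole_suspension": Strategy(
            "posaconazole_suspension",
            (Component("daily_cost_posa_susp", "duration_posa", 1.0),),
            "p_ifi_posaconazole",
        ),
        "posaconazole_tablet": Strategy(
            "posaconazole_tablet",
            (Component("daily_cost_posa_tab", "duration_posa", 1.0),),
            "p_ifi_posaconazole",
        ),
        "first_generation_triazoles": Strategy(
            "first_generation_triazoles",
            (
                Component("daily_cost_fluconazole", "duration_fluconazole", w),
                Component("daily_cost_itraconazole", "duration_itraconazole", 1.0 - w),
            ),
            "p_ifi_first_gen",
        ),
    }


@dataclass(frozen=True)
class TreeOutcome:
    """Terminal-state probabilities, expected costs, and initial accrual."""

    p_die_ifi: float
    p_die_other: float
    p_survive_post_ifi: float
    p_survive_no_ifi: float
    prophylaxis_cost: float
    ifi_management_cost: float
    initial_ly: float
    initial_qaly: float

    @property
    def survivor_fraction(self) -> float:
        return self.p_survive_post_ifi + self.p_survive_no_ifi


def prophylaxis_cost(strategy: Strategy, draw: Mapping[str, float]) -> float:
    """Expected drug-acquisition cost: sum of weight x daily cost x days."""
    return sum(
        c.weight * draw[c.cost] * draw[c.duration] for c in strategy.components
    )


def evaluate_tree(
    strategy: Strategy,
    draw: Mapping[str, float],
    settings: ModelSettings,
) -> TreeOutcome:
    """Evaluate the 100-day tree for one strategy under one parameter draw.

    Under the default ``exclusive`` topology the four terminal states are
    mutually exclusive splits: an IFI case dies of IFI or survives; a
    non-IFI patient dies of other causes or survives.  Under ``nested``,
    every patient not dying of IFI is additionally exposed to other-cause
    death.  IFI management cost attaches to IFI occurrence regardless of
    subsequent death.
    """
    p_ifi = draw[strategy.p_ifi_parameter]
    p_death_ifi = draw["p_death_ifi"]
    p_death_other = draw["p_death_other"]

    p_die_ifi = p_ifi * p_death_ifi
    if settings.tree_topology == "exclusive":
        p_survive_post_ifi = p_ifi * (1.0 - p_death_ifi)
        p_die_other = (1.0 - p_ifi) * p_death_other
        p_survive_no_ifi = (1.0 - p_ifi) * (1.0 - p_death_other)
    else:  # nested
        p_survive_post_ifi = p_ifi * (1.0 - p_death_ifi) * (1.0 - p_death_other)
        p_die_other = (1.0 - p_die_ifi) * p_death_other
        p_survive_no_ifi = (1.0 - p_ifi) * (1.0 - p_death_other)

    survivors = p_survive_post_ifi + p_survive_no_ifi
    initial_ly = settings.initial_period_days / DAYS_PER_YEAR
    if settings.initial_accrual == "half_for_decedents":
        initial_ly *= survivors + 0.5 * (1.0 - survivors)

    return TreeOutcome(
        p_die_ifi=p_die_ifi,
        p_die_other=p_die_other,
        p_survive_post_ifi=p_survive_post_ifi,
        p_survive_no_ifi=p_survive_no_ifi,
        prophylaxis_cost=prophylaxis_cost(strategy, draw),
        ifi_management_cost=p_ifi * draw["cost_ifi_treatment"],
        initial_ly=initial_ly,
        initial_qaly=initial_ly * draw["utility_induction"],
    )
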