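"""Per-strategy totals and incremental cost-effectiveness.

Combines the 100-day tree with the lifetime Markov phase: total cost is
drug acquisition plus expected IFI management (undiscounted); life-years
and QALYs are the initial-period accrual plus the survivor fraction times
the discounted per-survivor Markov expectation.  Incremental results and
ICERs are computed from unrounded internal values; report rounding (0.1
USD, 0.001 LY/QALY) is applied only in the output table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .decision_tree import Strategy, builtin_strategies, evaluate_tree
from .markov_cohort import per_survivor_expectation
from .parameters import ModelSettings, ParameterSet, base_case_draw

__all__ = [
    "StrategyResult",
    "CEAComparison",
    "evaluate_strategy",
    "compare_strategies",
    "net_monetary_benefit",
    "basecase_table",
]


@dataclass(frozen=True)
class StrategyResult:
    strategy: str
    drug_cost: float
    ifi_cost: float
    ly: float
    qaly: float

    @property
    def total_cost(self) -> float:
        return self.drug_cost + self.ifi_cost


@dataclass(frozen=True)
class CEAComparison:
    """Alternative minus reference; ICERs absent when undefined.

    ``dominance`` is "alt_dominant" when the alternative is at least as
    effective and cheaper (strictly better on one axis), "ref_dominant"
    for the mirror case, else "none".  ``southwest`` flags an ICER formed
    from a cheaper-and-less-effective comparison, where a larger ratio is
    favourable to the alternative.
    """

    delta_cost: float
    delta_ly: float
    delta_qaly: float
    icer_per_ly: float | None
    icer_per_qaly: float | None
    dominance: str
    southwest: bool = False


def evaluate_strategy(
    strategy: Strategy,
    draw: Mapping[str, float],
    settings: ModelSettings,
) -> StrategyResult:
    """Full tree + Markov evaluation of one strategy under one draw."""
    tree = evaluate_tree(strategy, draw, settings)
    markov_ly, markov_qaly = per_survivor_expectation(draw, settings)
    sf = tree.survivor_fraction
    return StrategyResult(
        strategy=strategy.name,
        drug_cost=tree.prophylaxis_cost,
        ifi_cost=tree.ifi_management_cost,
        ly=tree.initial_ly + sf * markov_ly,
        qaly=tree.initial_qaly + sf * markov_qaly,
    )


def _ratio(delta_cost: float, delta_effect: float) -> float | None:
    if delta_effect == 0.0 or not math.copysign(1, delta_cost) == math.copysign(
        1, delta_effect
    ):
        return None
    return delta_cost / delta_effect


def compare_strategies(
    reference: StrategyResult, alternative: StrategyResult
) -> CEAComparison:
    """Incremental results of the alternative vs. the reference regimen."""
    dc = alternative.total_cost - reference.total_cost
    dly = alternative.ly - reference.ly
    dq = alternative.qaly - reference.qaly

    if dc <= 0.0 and dq >= 0.0 and (dc < 0.0 or dq > 0.0):
        dominance = "alt_dominant"
    elif dc >= 0.0 and dq <= 0.0 and (dc > 0.0 or dq < 0.0):
        dominance = "ref_dominant"
    else:
        dominance = "none"

    southwest = dc < 0.0 and dq < 0.0
    icer_q = _ratio(dc, dq) if dominance == "none" else None
    icer_ly = _ratio(dc, dly) if dominance == "none" else None
    return CEAComparison(
        delta_cost=dc,
        delta_ly=dly,
        delta_qaly=dq,
        icer_per_ly=icer_ly,
        icer_per_qaly=icer_q,
        dominance=dominance,
        southwest=southwest,
    )


def net_monetary_benefit(result: StrategyResult, wtp: float) -> float:
    """NMB = WTP x QALY - total cost; higher is better at that WTP."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * result.qaly - result.total_cost


_ROW_ORDER = [
    "Total costs ($)",
    "Drug costs for prophylaxis ($)",
    "IFI management costs ($)",
    "LYs",
    "QALYs",
    "Incremental costs ($)",
    "Incremental LYs",
    "Incremental QALYs",
    "ICER ($/LY)",
    "ICER ($/QALY)",
]


def basecase_table(
    params: ParameterSet, settings: ModelSettings
) -> pd.DataFrame:
    """Base-case results table: one column per regimen, incremental rows
    taken against the first-generation-triazole reference.

    Costs and ICERs are rounded to 0.1, LY/QALY to 0.001.
    """
    draw = base_case_draw(params)
    strategies = builtin_strategies(settings)
    ref = evaluate_strategy(
        strategies["first_generation_triazoles"], draw, settings
    )
    columns: dict[str, dict[str, float | None]] = {}
    for label, key in (
        ("first_generation_triazoles", "first_generation_triazoles"),
        ("posaconazole_suspension", "posaconazole_suspension"),
        ("posaconazole_tablet", "posaconazole_tablet"),
    ):
        res = evaluate_strategy(strategies[key], draw, settings)
        col: dict[str, float | None] = {
            "Total costs ($)": round(res.total_cost, 1),
            "Drug costs for prophylaxis ($)": round(res.drug_cost, 1),
            "IFI management costs ($)": round(res.ifi_cost, 1),
            "LYs": round(res.ly, 3),
            "QALYs": round(res.qaly, 3),
        }
        if key == "first_generation_triazoles":
            col.update(
                {
                    "Incremental costs ($)": None,
                    "Incremental LYs": None,
                    "Incremental QALYs": None,
                    "ICER ($/LY)": None,
                    "ICER ($/QALY)": None,
                }
            )
        else:
            cmp = compare_strategies(ref, res)
            col.update(
                {
                    "Incremental costs ($)": round(cmp.delta_cost, 1),
                    "Incremental LYs": round(cmp.delta_ly, 3),
                    "Incremental QALYs": round(cmp.delta_qaly, 3),
                    "ICER ($/LY)": None
                    if cmp.icer_per_ly is None
                    else round(cmp.icer_per_ly, 1),
                    "ICER ($/QALY)": None
                    if cmp.icer_per_qaly is None
                    else round(cmp.icer_per_qaly, 1),
                }
            )
        columns[label] = col
    return pd.DataFrame(columns).reindex(_ROW_ORDER)
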