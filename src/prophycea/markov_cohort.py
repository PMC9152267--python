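"""Lifetime two-state (alive/dead) Markov cohort model for 100-day survivors.

The 5-year relative survival for each disease subgroup (AML, MDS) is
converted to a constant monthly death probability, 1 - S5^(1/60), which is
extrapolated unchanged beyond five years — no cure point and no background
mortality table.  Cycles are monthly with a trapezoidal half-cycle
correction (half weight on the first and last cycle).  Benefits
(life-years and QALYs) are discounted at the annual rate compounded
monthly; the discounting clock starts at Markov entry, i.e. the initial
100-day period is undiscounted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .parameters import ModelSettings

__all__ = [
    "MarkovTrace",
    "monthly_death_probability",
    "run_cohort",
    "per_survivor_expectation",
    "trace_to_frame",
]

MONTHS_PER_5Y = 60
MONTHS_PER_YEAR = 12


def monthly_death_probability(five_year_survival: float) -> float:
    """Constant monthly death probability implied by a 5-year survival."""
    if not 0.0 < five_year_survival <= 1.0:
        raise ValueError(
            f"five-year survival must lie in (0, 1], got {five_year_survival}"
        )
    return 1.0 - five_year_survival ** (1.0 / MONTHS_PER_5Y)


@dataclass(frozen=True)
class MarkovTrace:
    """Cohort trace and its discounted per-survivor totals."""

    alive: np.ndarray  # proportion alive at cycles 0..T
    discounted_ly: float  # years per entering survivor
    discounted_qaly: float
    annual_discount: float
    utility: float


def run_cohort(
    monthly_p: float,
    horizon_cycles: int,
    annual_discount: float,
    utility: float,
) -> MarkovTrace:
    """Run the two-state cohort to the horizon.

    alive[t] = (1 - monthly_p)^t; discounted life-years are the
    half-cycle-corrected sum (1/12) * [1/2*alive[0] + sum_{t=1}^{T-1}
    alive[t] v^t + 1/2*alive[T] v^T] with v = (1 + r)^(-1/12).
    """
    if horizon_cycles < 1:
        raise ValueError("horizon_cycles must be >= 1")
    t = np.arange(horizon_cycles + 1)
    alive = (1.0 - monthly_p) ** t
    v = (1.0 + annual_discount) ** (-1.0 / MONTHS_PER_YEAR)
    weights = np.ones(horizon_cycles + 1)
    weights[0] = weights[-1] = 0.5
    months = float(np.sum(weights * alive * v**t))
    ly = months / MONTHS_PER_YEAR
    return MarkovTrace(
        alive=alive,
        discounted_ly=ly,
        discounted_qaly=ly * utility,
        annual_discount=annual_discount,
        utility=utility,
    )


def per_survivor_expectation(
    draw: Mapping[str, float],
    settings: ModelSettings,
) -> tuple[float, float]:
    """Expected (LY, QALY) per 100-day survivor, mixed over AML/MDS.

    The cohort is an aml_share : (1 - aml_share) mixture of the two
    disease subgroups, each run with the remission utility.
    """
    ly = 0.0
    qaly = 0.0
    for share, surv_key in (
        (settings.aml_share, "surv5_aml"),
        (1.0 - settings.aml_share, "surv5_mds"),
    ):
        if share == 0.0:
            continue
        trace = run_cohort(
            monthly_death_probability(draw[surv_key]),
            settings.horizon_cycles,
            draw["discount_rate"],
            draw["utility_remission"],
        )
        ly += share * trace.discounted_ly
        qaly += share * trace.discounted_qaly
    return ly, qaly


def trace_to_frame(trace: MarkovTrace) -> pd.DataFrame:
    """Per-cycle trace as a table: membership, discounting, accrual."""
    T = len(trace.alive) - 1
    t = np.arange(T + 1)
    v = (1.0 + trace.annual_discount) ** (-t / MONTHS_PER_YEAR)
    weights = np.ones(T + 1)
    weights[0] = weights[-1] = 0.5
    cycle_ly = weights * trace.alive * v / MONTHS_PER_YEAR
    return pd.DataFrame(
        {
            "cycle": t,
            "alive_proportion": trace.alive,
            "discount_factor": v,
            "cycle_ly": cycle_ly,
            "cycle_qaly": cycle_ly * trace.utility,
        }
    )
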