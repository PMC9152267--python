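"""Sensitivity analyses: one-way deterministic (tornado), probabilistic
Monte Carlo, cost-effectiveness probability, and acceptability curves.

The one-way analysis moves each input to the ends of its stated range
(or base +/- 25% when none is stated) with everything else at base, and
records the ICER at each end.  The probabilistic analysis redraws every
input jointly from its fitted distribution and pushes each draw through
the full tree + Markov pipeline; cost-effectiveness at a willingness-to-
pay threshold is judged per iteration on incremental net monetary
benefit, which stays well defined when the QALY difference crosses zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cea_engine import compare_strategies, evaluate_strategy
from .decision_tree import Strategy
from .parameters import (
    DistributionSpec,
    ModelSettings,
    Parameter,
    ParameterSet,
    base_case_draw,
    draw_from_rng,
    dsa_bounds,
)

__all__ = [
    "TornadoEntry",
    "PSAResult",
    "CEACPoint",
    "one_way_dsa",
    "run_psa",
    "probability_cost_effective",
    "ceac",
    "default_wtp_grid",
    "tornado_frame",
    "psa_frame",
    "ceac_frame",
    "plot_tornado",
    "plot_scatter",
    "plot_ceac",
]


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low: float
    high: float
    icer_at_low: float
    icer_at_high: float

    @property
    def width(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


@dataclass(frozen=True)
class PSAResult:
    """Per-iteration incremental outcomes of alternative vs. reference."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    delta_ly: np.ndarray
    seed: int

    @property
    def n_iterations(self) -> int:
        return len(self.delta_cost)


@dataclass(frozen=True)
class CEACPoint:
    wtp: float
    probability_cost_effective: float


def _icer_at(
    params: ParameterSet,
    settings: ModelSettings,
    pair: tuple[Strategy, Strategy],
    param: Parameter,
    value: float,
) -> float:
    """ICER per QALY with one parameter pinned to ``value``."""
    spec = param.spec
    pinned = Parameter(
        param.name,
        param.units,
        DistributionSpec(
            spec.family, value, min(spec.low, value), max(spec.high, value)
        ),
        None,
    )
    draw = base_case_draw(params.with_parameter(pinned))
    reference, alternative = pair
    cmp = compare_strategies(
        evaluate_strategy(reference, draw, settings),
        evaluate_strategy(alternative, draw, settings),
    )
    return math.nan if cmp.icer_per_qaly is None else cmp.icer_per_qaly


def one_way_dsa(
    params: ParameterSet,
    settings: ModelSettings,
    pair: tuple[Strategy, Strategy],
) -> list[TornadoEntry]:
    """Tornado entries for every tunable input, widest bar first.

    Structural constants (cohort shares, horizon, WTP) are not varied.
    Ties in width are broken alphabetically by parameter name.
    """
    entries = []
    for param in params:
        low, high = dsa_bounds(param)
        entries.append(
            TornadoEntry(
                parameter=param.name,
                low=low,
                high=high,
                icer_at_low=_icer_at(params, settings, pair, param, low),
                icer_at_high=_icer_at(params, settings, pair, param, high),
            )
        )
    return sorted(entries, key=lambda e: (-e.width, e.parameter))


def run_psa(
    params: ParameterSet,
    settings: ModelSettings,
    pair: tuple[Strategy, Strategy],
    n_iterations: int | None = None,
    seed: int | None = None,
) -> PSAResult:
    """Monte Carlo simulation over joint parameter draws.

    Iteration count and seed default to the settings (1,000 iterations).
    The same (seed, n) reproduces the result exactly.
    """
    n = settings.psa_iterations if n_iterations is None else n_iterations
    if n < 1:
        raise ValueError("n_iterations must be >= 1")
    s = settings.rng_seed if seed is None else seed
    rng = np.random.default_rng(s)
    reference, alternative = pair
    dc = np.empty(n)
    dq = np.empty(n)
    dly = np.empty(n)
    for i in range(n):
        draw = draw_from_rng(params, rng)
        ref = evaluate_strategy(reference, draw, settings)
        alt = evaluate_strategy(alternative, draw, settings)
        dc[i] = alt.total_cost - ref.total_cost
        dq[i] = alt.qaly - ref.qaly
        dly[i] = alt.ly - ref.ly
    return PSAResult(delta_cost=dc, delta_qaly=dq, delta_ly=dly, seed=s)


def probability_cost_effective(psa: PSAResult, wtp: float) -> float:
    """Fraction of iterations with positive incremental net benefit."""
    return float(np.mean(wtp * psa.delta_qaly - psa.delta_cost > 0.0))


def default_wtp_grid() -> np.ndarray:
    return np.arange(0.0, 60_000.0 + 1.0, 250.0)


def ceac(psa: PSAResult, wtp_grid) -> list[CEACPoint]:
    """Cost-effectiveness acceptability curve over an ascending WTP grid."""
    return [
        CEACPoint(float(w), probability_cost_effective(psa, float(w)))
        for w in wtp_grid
    ]


# ---------------------------------------------------------------------------
# tabular / graphical export


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "low": [e.low for e in entries],
            "high": [e.high for e in entries],
            "icer_low": [e.icer_at_low for e in entries],
            "icer_high": [e.icer_at_high for e in entries],
            "width": [e.width for e in entries],
        }
    )


def psa_frame(psa: PSAResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "iteration": np.arange(psa.n_iterations),
            "delta_cost": psa.delta_cost,
            "delta_ly": psa.delta_ly,
            "delta_qaly": psa.delta_qaly,
        }
    )


def ceac_frame(points: list[CEACPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "wtp": [p.wtp for p in points],
            "probability_cost_effective": [
                p.probability_cost_effective for p in points
            ],
        }
    )


def plot_tornado(entries: list[TornadoEntry], base_icer: float, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shown = [e for e in entries if e.width > 0][::-1]
    fig, ax = plt.subplots(figsize=(7, 0.4 * max(len(shown), 4) + 1))
    for i, e in enumerate(shown):
        lo = min(e.icer_at_low, e.icer_at_high)
        ax.barh(i, e.width, left=lo, color="#4878d0")
    ax.axvline(base_icer, color="k", lw=1, ls="--", label="base-case ICER")
    ax.set_yticks(range(len(shown)))
    ax.set_yticklabels([e.parameter for e in shown])
    ax.set_xlabel("ICER ($/QALY)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_scatter(psa: PSAResult, wtp: float, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(psa.delta_qaly, psa.delta_cost, s=6, alpha=0.4)
    lim = float(np.max(np.abs(psa.delta_qaly))) * 1.05
    xs = np.linspace(-lim, lim, 2)
    ax.plot(xs, wtp * xs, "k--", lw=1, label=f"WTP ${wtp:,.0f}/QALY")
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost ($)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(points: list[CEACPoint], path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot([p.wtp for p in points], [p.probability_cost_effective for p in points])
    ax.set_ylim(0, 1)
    ax.set_xlabel("Willingness to pay ($/QALY)")
    ax.set_ylabel("Probability cost-effective")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
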