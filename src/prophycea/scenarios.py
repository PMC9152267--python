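"""Scenario analyses.

Two scenarios beyond the base case: (i) substituting the posaconazole
tablet formulation for the oral suspension — equal prophylactic efficacy
and duration, only the daily drug cost changes; (ii) re-judging
cost-effectiveness under province-level willingness-to-pay thresholds,
each set at three times the province's GDP per capita (CNY inputs are
converted at the published exchange rate of 689.76 yuan per 100 USD).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cea_engine import CEAComparison
from .decision_tree import Strategy, builtin_strategies
from .parameters import ModelSettings, ParameterSet
from .sensitivity import PSAResult, probability_cost_effective

__all__ = [
    "ProvinceRecord",
    "ProvinceResult",
    "ScenarioReport",
    "tablet_strategy",
    "province_analysis",
    "load_province_table",
    "provinces_to_frame",
]

WTP_GDP_MULTIPLE = 3.0


@dataclass(frozen=True)
class ProvinceRecord:
    province: str
    gdp_per_capita: float  # USD

    def __post_init__(self) -> None:
        if not self.gdp_per_capita > 0:
            raise ValueError(
                f"{self.province}: gdp_per_capita must be > 0, "
                f"got {self.gdp_per_capita}"
            )

    @property
    def wtp(self) -> float:
        return WTP_GDP_MULTIPLE * self.gdp_per_capita


@dataclass(frozen=True)
class ProvinceResult:
    province: str
    wtp: float
    base_icer_below_wtp: bool
    psa_probability: float


@dataclass(frozen=True)
class ScenarioReport:
    results: tuple[ProvinceResult, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "province": [r.province for r in self.results],
                "wtp": [r.wtp for r in self.results],
                "base_icer_below_wtp": [r.base_icer_below_wtp for r in self.results],
                "psa_probability": [r.psa_probability for r in self.results],
            }
        )


def tablet_strategy(
    params: ParameterSet, settings: ModelSettings | None = None
) -> Strategy:
    """The tablet formulation: same efficacy and 29-day duration as the
    suspension, at the tablet daily cost applied flat over all days."""
    return builtin_strategies(settings or ModelSettings())["posaconazole_tablet"]


def province_analysis(
    base: CEAComparison,
    psa: PSAResult,
    provinces: list[ProvinceRecord] | tuple[ProvinceRecord, ...],
) -> ScenarioReport:
    """Judge the base-case ICER and the PSA against each province's WTP."""
    results = []
    for rec in provinces:
        below = base.icer_per_qaly is not None and base.icer_per_qaly <= rec.wtp
        if base.dominance == "alt_dominant":
            below = True
        results.append(
            ProvinceResult(
                province=rec.province,
                wtp=rec.wtp,
                base_icer_below_wtp=below,
                psa_probability=probability_cost_effective(psa, rec.wtp),
            )
        )
    return ScenarioReport(results=tuple(results))


def load_province_table(path, settings: ModelSettings | None = None) -> list[ProvinceRecord]:
    """Read a province GDP table (CSV: province, gdp_per_capita, currency).

    ``currency`` is USD or CNY; CNY values are converted once at load.
    """
    settings = settings or ModelSettings()
    df = pd.read_csv(path)
    required = {"province", "gdp_per_capita"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"province table missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        gdp = float(row["gdp_per_capita"])
        currency = str(row.get("currency", "USD")).upper()
        if currency == "CNY":
            gdp *= 100.0 / settings.cny_per_100usd
        elif currency != "USD":
            raise ValueError(f"unknown currency {currency!r}")
        records.append(ProvinceRecord(str(row["province"]), gdp))
    return records


def provinces_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "province": [r.province for r in records],
            "gdp_per_capita": [r.gdp_per_capita for r in records],
            "currency": ["USD"] * len(records),
        }
    )
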