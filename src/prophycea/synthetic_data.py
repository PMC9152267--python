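"""Synthetic inputs with the statistical structure the model assumes.

Two generators: (i) RCT-like outcome counts — IFI events per arm at the
published arm sizes (304 posaconazole, 298 first-generation triazoles),
with IFI deaths drawn among the IFI cases and other-cause deaths among
the rest (hierarchical binomials, mirroring how the published
probabilities nest); (ii) a province-level GDP-per-capita table for
willingness-to-pay sweeps.  A paired estimator recovers the tree
probabilities from simulated counts, pooling the mortality terms across
arms the way the published analysis does, which supports parameter-
recovery and end-to-end testing without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import DistributionSpec, Parameter, ParameterSet
from .scenarios import ProvinceRecord

__all__ = [
    "ArmCounts",
    "TrialCounts",
    "TrialEstimates",
    "simulate_trial",
    "estimate_parameters",
    "apply_estimates",
    "make_province_table",
]

DEFAULT_N_POSA = 304
DEFAULT_N_FGT = 298


@dataclass(frozen=True)
class ArmCounts:
    n: int
    ifi_events: int
    deaths_ifi: int  # among IFI cases
    deaths_other: int  # among non-IFI patients

    def __post_init__(self) -> None:
        if not 0 <= self.ifi_events <= self.n:
            raise ValueError("ifi_events must lie in [0, n]")
        if not 0 <= self.deaths_ifi <= self.ifi_events:
            raise ValueError("deaths_ifi must lie in [0, ifi_events]")
        if not 0 <= self.deaths_other <= self.n - self.ifi_events:
            raise ValueError("deaths_other must lie in [0, n - ifi_events]")


@dataclass(frozen=True)
class TrialCounts:
    posaconazole: ArmCounts
    first_generation: ArmCounts


def simulate_trial(
    n_posa: int,
    n_fgt: int,
    truth: ParameterSet,
    seed: int,
) -> TrialCounts:
    """Simulate one two-arm prophylaxis trial at the given truth.

    IFI events are binomial per arm; IFI deaths are binomial among the
    simulated IFI cases and other-cause deaths among the remainder.
    """
    if n_posa < 0 or n_fgt < 0:
        raise ValueError("arm sizes must be >= 0")
    rng = np.random.default_rng(seed)
    p_death_ifi = truth.p_death_ifi.value
    p_death_other = truth.p_death_other.value
    arms = []
    for n, p_ifi in (
        (n_posa, truth.p_ifi_posaconazole.value),
        (n_fgt, truth.p_ifi_first_gen.value),
    ):
        events = int(rng.binomial(n, p_ifi))
        arms.append(
            ArmCounts(
                n=n,
                ifi_events=events,
                deaths_ifi=int(rng.binomial(events, p_death_ifi)),
                deaths_other=int(rng.binomial(n - events, p_death_other)),
            )
        )
    return TrialCounts(posaconazole=arms[0], first_generation=arms[1])


@dataclass(frozen=True)
class TrialEstimates:
    """Probabilities estimated from trial counts; ``missing`` names the
    quantities whose denominator was zero."""

    p_ifi_posaconazole: Parameter | None
    p_ifi_first_gen: Parameter | None
    p_death_ifi: Parameter | None
    p_death_other: Parameter | None
    missing: tuple[str, ...]


def _estimated(name: str, events: int, n: int) -> Parameter:
    est = events / n
    low = 0.75 * est
    high = min(1.25 * est, 1.0)
    return Parameter(
        name,
        "probability",
        DistributionSpec("beta" if 0 < est < 1 else "fixed", est, low, high),
        source_counts=(events, n),
    )


def estimate_parameters(counts: TrialCounts) -> TrialEstimates:
    """Tree probabilities from counts; mortalities pooled across arms.

    Per-arm IFI probability is events/n.  IFI-related mortality and
    other-cause mortality are each pooled over both arms (the published
    analysis assumes them equal between arms).  Ranges are set to
    +/- 25% of the estimate, capped at 1.
    """
    a, b = counts.posaconazole, counts.first_generation
    estimates: dict[str, Parameter | None] = {}
    missing: list[str] = []

    for name, events, n in (
        ("p_ifi_posaconazole", a.ifi_events, a.n),
        ("p_ifi_first_gen", b.ifi_events, b.n),
        ("p_death_ifi", a.deaths_ifi + b.deaths_ifi, a.ifi_events + b.ifi_events),
        (
            "p_death_other",
            a.deaths_other + b.deaths_other,
            (a.n - a.ifi_events) + (b.n - b.ifi_events),
        ),
    ):
        if n == 0:
            estimates[name] = None
            missing.append(name)
        else:
            estimates[name] = _estimated(name, events, n)

    return TrialEstimates(missing=tuple(missing), **estimates)


def apply_estimates(params: ParameterSet, estimates: TrialEstimates) -> ParameterSet:
    """Overlay available trial estimates onto a full parameter set."""
    out = params
    for name in (
        "p_ifi_posaconazole",
        "p_ifi_first_gen",
        "p_death_ifi",
        "p_death_other",
    ):
        est = getattr(estimates, name)
        if est is not None:
            out = out.with_parameter(est)
    return out


def make_province_table(
    n_provinces: int,
    gdp_range: tuple[float, float],
    seed: int,
) -> list[ProvinceRecord]:
    """Synthetic province GDP table, uniform on the given USD range."""
    low, high = gdp_range
    if n_provinces < 0:
        raise ValueError("n_provinces must be >= 0")
    if low > high or low <= 0:
        raise ValueError("gdp_range must satisfy 0 < low <= high")
    rng = np.random.default_rng(seed)
    gdp = rng.uniform(low, high, size=n_provinces)
    return [
        ProvinceRecord(f"province_{i + 1:02d}", float(g))
        for i, g in enumerate(gdp)
    ]
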