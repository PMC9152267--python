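"""Model inputs for the antifungal-prophylaxis cost-effectiveness model.

Every quantity the model consumes lives here: the clinical probabilities
from the pivotal prophylaxis trial (posaconazole oral suspension vs.
first-generation triazoles in AML/MDS patients), 5-year relative survival
for the two disease subgroups, 2020-USD unit costs, prophylaxis durations,
health-state utilities, and the structural constants (cohort composition,
cycle structure, willingness-to-pay threshold).

Each tunable input carries a base-case value, a deterministic-sensitivity
range, and a sampling-distribution family for probabilistic sensitivity
analysis.  Beta and gamma distributions are moment-matched so that their
analytic mean equals the base value and their standard deviation equals
(high - low) / 3.92, i.e. the range is treated as a 95% interval.
"""

from __future__ import annotations

import dataclasses
import math
import os
from dataclasses import dataclass, replace
from typing import Iterator, Mapping

import numpy as np
import yaml

__all__ = [
    "DistributionSpec",
    "Parameter",
    "ParameterSet",
    "ModelSettings",
    "SamplingDistribution",
    "ConfigError",
    "default_parameters",
    "load_parameters",
    "export_parameters",
    "base_case_draw",
    "dsa_bounds",
    "fit_sampling_distribution",
    "sample_parameter_set",
    "draw_from_rng",
]

FAMILIES = ("beta", "uniform", "gamma", "fixed")

#: units whose sampled values are clipped to the unit interval
_UNIT_INTERVAL_UNITS = ("probability", "utility")


class ConfigError(ValueError):
    """Raised when a configuration document fails schema validation."""


@dataclass(frozen=True)
class DistributionSpec:
    """Base value, range, and sampling family for one model input."""

    family: str
    base: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigError(
                f"unknown distribution family {self.family!r}; "
                f"expected one of {FAMILIES}"
            )
        if not (self.low <= self.base <= self.high):
            raise ConfigError(
                f"range error: low <= base <= high violated "
                f"({self.low}, {self.base}, {self.high})"
            )
        if self.family == "beta" and not (0.0 <= self.low and self.high <= 1.0):
            raise ConfigError(
                f"beta range must lie in [0, 1], got ({self.low}, {self.high})"
            )
        if self.family == "gamma" and not self.low > 0.0:
            raise ConfigError(f"gamma requires low > 0, got {self.low}")


@dataclass(frozen=True)
class Parameter:
    """A named model input.

    ``value`` is the number the base case actually uses.  When the input
    derives from printed trial counts (``source_counts``) the unrounded
    fraction events/n is used, which is what reproduces the published
    cost cells; otherwise ``value`` equals the printed base.
    """

    name: str
    units: str  # probability | utility | USD | USD/day | days | rate
    spec: DistributionSpec
    source_counts: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.units in _UNIT_INTERVAL_UNITS and not 0.0 <= self.value <= 1.0:
            raise ConfigError(
                f"{self.name}: {self.units} value {self.value} outside [0, 1]"
            )
        if self.units in ("USD", "USD/day", "days") and self.value < 0:
            raise ConfigError(f"{self.name}: {self.units} value must be >= 0")
        if self.source_counts is not None:
            events, n = self.source_counts
            if not (0 <= events <= n and n > 0):
                raise ConfigError(
                    f"{self.name}: invalid source counts {self.source_counts}"
                )

    @property
    def value(self) -> float:
        if self.source_counts is not None:
            events, n = self.source_counts
            return events / n
        return self.spec.base


@dataclass(frozen=True)
class ParameterSet:
    """The complete input table (all 17 tunable rows)."""

    p_ifi_posaconazole: Parameter
    p_ifi_first_gen: Parameter
    p_death_ifi: Parameter
    p_death_other: Parameter
    surv5_aml: Parameter
    surv5_mds: Parameter
    cost_ifi_treatment: Parameter
    daily_cost_posa_susp: Parameter
    daily_cost_posa_tab: Parameter
    daily_cost_fluconazole: Parameter
    daily_cost_itraconazole: Parameter
    duration_posa: Parameter
    duration_fluconazole: Parameter
    duration_itraconazole: Parameter
    discount_rate: Parameter
    utility_induction: Parameter
    utility_remission: Parameter

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            p = getattr(self, f.name)
            if p is None:
                raise ConfigError(f"parameter set incomplete: missing {f.name}")
            if p.name != f.name:
                raise ConfigError(
                    f"parameter name mismatch: field {f.name} holds {p.name}"
                )

    @classmethod
    def names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))

    def __iter__(self) -> Iterator[Parameter]:
        for f in dataclasses.fields(self):
            yield getattr(self, f.name)

    def get(self, name: str) -> Parameter:
        if name not in self.names():
            raise KeyError(name)
        return getattr(self, name)

    def with_parameter(self, param: Parameter) -> "ParameterSet":
        """Return a copy with one entry replaced (matched by name)."""
        return replace(self, **{param.name: param})


@dataclass(frozen=True)
class ModelSettings:
    """Structural constants not subject to sensitivity analysis.

    The cohort is 86% AML / 14% MDS; within the comparator arm 81% of
    patients receive fluconazole and the rest itraconazole.  The decision
    tree covers the initial 100 days; survivors then enter a monthly-cycle
    lifetime Markov model (600 cycles = 50 years by default, long enough
    that the cohort is numerically extinct under base-case hazards).
    """

    initial_period_days: float = 100.0
    cycle_length_months: float = 1.0
    horizon_cycles: int = 600
    aml_share: float = 0.86
    fluconazole_share: float = 0.81
    wtp_per_qaly: float = 31_315.0
    cny_per_100usd: float = 689.76
    psa_iterations: int = 1000
    rng_seed: int = 1234
    # tree_topology "exclusive": IFI death and other-cause death are
    # mutually exclusive branches.  "nested": every patient not dying of
    # IFI is additionally exposed to other-cause death.
    tree_topology: str = "exclusive"
    # initial_accrual "full": all patients accrue the full 100-day
    # LY/QALY; "half_for_decedents": within-period decedents accrue half.
    initial_accrual: str = "full"

    def __post_init__(self) -> None:
        if not 0.0 <= self.aml_share <= 1.0:
            raise ConfigError(f"aml_share {self.aml_share} outside [0, 1]")
        if not 0.0 <= self.fluconazole_share <= 1.0:
            raise ConfigError(
                f"fluconazole_share {self.fluconazole_share} outside [0, 1]"
            )
        if self.horizon_cycles < 1:
            raise ConfigError("horizon_cycles must be >= 1")
        if self.wtp_per_qaly < 0:
            raise ConfigError("wtp_per_qaly must be >= 0")
        if self.tree_topology not in ("exclusive", "nested"):
            raise ConfigError(f"unknown tree_topology {self.tree_topology!r}")
        if self.initial_accrual not in ("full", "half_for_decedents"):
            raise ConfigError(f"unknown initial_accrual {self.initial_accrual!r}")


def _p(name, units, family, base, low, high, counts=None) -> Parameter:
    return Parameter(name, units, DistributionSpec(family, base, low, high), counts)


def default_parameters() -> tuple[ParameterSet, ModelSettings]:
    """The published base-case input table and structural constants.

    Probabilities backed by printed trial counts (IFI occurrence 14/304
    and 33/298; pooled IFI mortality (5+16)/(14+33)) carry those counts so
    the base case uses the unrounded fractions.
    """
    params = ParameterSet(
        p_ifi_posaconazole=_p(
            "p_ifi_posaconazole", "probability", "beta", 0.046, 0.034, 0.058,
            counts=(14, 304),
        ),
        p_ifi_first_gen=_p(
            "p_ifi_first_gen", "probability", "beta", 0.111, 0.083, 0.139,
            counts=(33, 298),
        ),
        p_death_ifi=_p(
            "p_death_ifi", "probability", "beta", 0.447, 0.335, 0.559,
            counts=(21, 47),
        ),
        p_death_other=_p(
            "p_death_other", "probability", "beta", 0.158, 0.119, 0.198,
        ),
        surv5_aml=_p("surv5_aml", "probability", "uniform", 0.44, 0.33, 0.55),
        surv5_mds=_p("surv5_mds", "probability", "uniform", 0.52, 0.39, 0.65),
        cost_ifi_treatment=_p(
            "cost_ifi_treatment", "USD", "uniform", 5423.3, 4067.5, 6779.1,
        ),
        daily_cost_posa_susp=_p(
            "daily_cost_posa_susp", "USD/day", "uniform", 45.56, 34.17, 56.95,
        ),
        daily_cost_posa_tab=_p(
            "daily_cost_posa_tab", "USD/day", "uniform", 119.98, 89.99, 149.98,
        ),
        daily_cost_fluconazole=_p(
            "daily_cost_fluconazole", "USD/day", "uniform", 0.26, 0.20, 0.33,
        ),
        daily_cost_itraconazole=_p(
            "daily_cost_itraconazole", "USD/day", "uniform", 1.89, 1.42, 2.36,
        ),
        duration_posa=_p("duration_posa", "days", "gamma", 29.0, 21.75, 36.25),
        duration_fluconazole=_p(
            "duration_fluconazole", "days", "gamma", 24.0, 18.00, 30.00,
        ),
        duration_itraconazole=_p(
            "duration_itraconazole", "days", "gamma", 29.0, 21.75, 36.25,
        ),
        discount_rate=_p("discount_rate", "rate", "uniform", 0.05, 0.0, 0.08),
        utility_induction=_p(
            "utility_induction", "utility", "uniform", 0.648, 0.486, 0.810,
        ),
        utility_remission=_p(
            "utility_remission", "utility", "uniform", 0.830, 0.623, 1.000,
        ),
    )
    return params, ModelSettings()


def base_case_draw(params: ParameterSet) -> dict[str, float]:
    """Deterministic draw at base-case values (unrounded where counts exist)."""
    return {p.name: p.value for p in params}


# ---------------------------------------------------------------------------
# deterministic sensitivity bounds


def dsa_bounds(param: Parameter) -> tuple[float, float]:
    """Low/high values for one-way sensitivity analysis.

    The stated range is used when one exists; otherwise base +/- 25%,
    with utilities truncated at 1.
    """
    spec = param.spec
    if spec.family == "fixed":
        return (spec.base, spec.base)
    if spec.low != spec.high:
        return (spec.low, spec.high)
    low, high = spec.base * 0.75, spec.base * 1.25
    if param.units == "utility":
        high = min(high, 1.0)
    return (low, high)


# ---------------------------------------------------------------------------
# sampling distributions


@dataclass(frozen=True)
class SamplingDistribution:
    """A constructed PSA distribution.

    Parameter meaning by family: beta -> (a, b) = (alpha, beta);
    gamma -> (a, b) = (shape, scale); uniform -> (a, b) = (low, high);
    fixed -> a = point mass, b unused.
    """

    family: str
    a: float
    b: float = 0.0

    def mean(self) -> float:
        if self.family == "beta":
            return self.a / (self.a + self.b)
        if self.family == "gamma":
            return self.a * self.b
        if self.family == "uniform":
            return 0.5 * (self.a + self.b)
        return self.a

    def sd(self) -> float:
        if self.family == "beta":
            s = self.a + self.b
            return math.sqrt(self.a * self.b / (s * s * (s + 1.0)))
        if self.family == "gamma":
            return math.sqrt(self.a) * self.b
        if self.family == "uniform":
            return (self.b - self.a) / math.sqrt(12.0)
        return 0.0

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "beta":
            return rng.beta(self.a, self.b, size=size)
        if self.family == "gamma":
            return rng.gamma(self.a, self.b, size=size)
        if self.family == "uniform":
            return rng.uniform(self.a, self.b, size=size)
        return self.a if size is None else np.full(size, self.a)


def fit_sampling_distribution(param: Parameter) -> SamplingDistribution:
    """Construct the PSA distribution for one parameter.

    Uniform rows sample uniformly on [low, high].  Beta and gamma rows are
    moment-matched: mean = base, sd = (high - low) / 3.92.  A degenerate
    range collapses to a point mass.
    """
    spec = param.spec
    if spec.family == "fixed":
        return SamplingDistribution("fixed", spec.base)
    if spec.family == "uniform":
        return SamplingDistribution("uniform", spec.low, spec.high)

    sd = (spec.high - spec.low) / 3.92
    if sd == 0.0:
        return SamplingDistribution("fixed", spec.base)
    var = sd * sd
    m = spec.base
    if spec.family == "beta":
        if not 0.0 < m < 1.0:
            raise ValueError(
                f"{param.name}: beta requires base in (0, 1), got {m}"
            )
        if var >= m * (1.0 - m):
            raise ValueError(
                f"{param.name}: variance {var:.3g} too large for a beta "
                f"distribution with mean {m}"
            )
        k = m * (1.0 - m) / var - 1.0
        return SamplingDistribution("beta", m * k, (1.0 - m) * k)
    # gamma
    if m <= 0.0:
        raise ValueError(f"{param.name}: gamma requires base > 0, got {m}")
    return SamplingDistribution("gamma", m * m / var, var / m)


def draw_from_rng(params: ParameterSet, rng: np.random.Generator) -> dict[str, float]:
    """One joint PSA draw; probabilities and utilities clipped to [0, 1]."""
    draw: dict[str, float] = {}
    for p in params:
        x = float(fit_sampling_distribution(p).sample(rng))
        if p.units in _UNIT_INTERVAL_UNITS:
            x = min(max(x, 0.0), 1.0)
        elif p.units in ("USD", "USD/day", "days", "rate"):
            x = max(x, 0.0)
        draw[p.name] = x
    return draw


def sample_parameter_set(params: ParameterSet, seed: int) -> dict[str, float]:
    """One seed-deterministic joint draw of all parameters."""
    return draw_from_rng(params, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# configuration documents

_PARAM_KEYS = {"family", "base", "low", "high", "counts"}
_REQUIRED_PARAM_KEYS = ("family", "base", "low", "high")
_SETTINGS_KEYS = {f.name for f in dataclasses.fields(ModelSettings)}


def export_parameters(params: ParameterSet, settings: ModelSettings) -> str:
    """Serialize a full configuration to YAML text (round-trips via load)."""
    doc: dict = {"parameters": {}, "settings": {}}
    for p in params:
        entry: dict = {
            "family": p.spec.family,
            "base": p.spec.base,
            "low": p.spec.low,
            "high": p.spec.high,
        }
        if p.source_counts is not None:
            entry["counts"] = list(p.source_counts)
        doc["parameters"][p.name] = entry
    for f in dataclasses.fields(ModelSettings):
        doc["settings"][f.name] = getattr(settings, f.name)
    return yaml.safe_dump(doc, sort_keys=False)


_UNITS = {}  # filled lazily from the defaults


def _default_units() -> dict[str, str]:
    if not _UNITS:
        defaults, _ = default_parameters()
        _UNITS.update({p.name: p.units for p in defaults})
    return _UNITS


def load_parameters(source) -> tuple[ParameterSet, ModelSettings]:
    """Load a configuration document on top of the defaults.

    ``source`` may be a mapping, a path to a YAML file, or YAML text.
    Overrides are validated strictly: unknown sections, parameter names,
    settings keys, or distribution families are rejected, and each
    overridden parameter must state family, base, low and high.
    """
    if isinstance(source, Mapping):
        doc = dict(source)
    else:
        text = None
        if isinstance(source, (str, os.PathLike)):
            s = os.fspath(source)
            if "\n" not in s and os.path.exists(s):
                with open(s) as fh:
                    text = fh.read()
            else:
                text = s
        else:  # file-like
            text = source.read()
        doc = yaml.safe_load(text) or {}
    if not isinstance(doc, Mapping):
        raise ConfigError("configuration document must be a mapping")

    unknown = set(doc) - {"parameters", "settings"}
    if unknown:
        raise ConfigError(f"unknown top-level sections: {sorted(unknown)}")

    params, settings = default_parameters()
    units = _default_units()

    for name, entry in (doc.get("parameters") or {}).items():
        if name not in ParameterSet.names():
            raise ConfigError(f"unknown parameter {name!r}")
        if not isinstance(entry, Mapping) or not entry:
            raise ConfigError(
                f"{name}: missing required field(s) {_REQUIRED_PARAM_KEYS}; "
                "a parameter entry must be a non-empty mapping"
            )
        bad = set(entry) - _PARAM_KEYS
        if bad:
            raise ConfigError(f"{name}: unknown keys {sorted(bad)}")
        default = params.get(name)
        # partial overrides merge over the default row; overriding the base
        # without restating counts drops the counts, so the new base is
        # actually what the base case uses
        if "counts" in entry:
            counts = entry["counts"]
            counts = None if counts is None else (int(counts[0]), int(counts[1]))
        elif "base" in entry:
            counts = None
        else:
            counts = default.source_counts
        base = float(entry.get("base", default.spec.base))
        if "base" in entry and "low" not in entry and "high" not in entry:
            # a bare base override invalidates the old range; collapse it so
            # dsa_bounds falls back to base +/- 25% and PSA to a point mass
            low = high = base
        else:
            low = float(entry.get("low", default.spec.low))
            high = float(entry.get("high", default.spec.high))
        param = Parameter(
            name,
            units[name],
            DistributionSpec(
                str(entry.get("family", default.spec.family)),
                base,
                low,
                high,
            ),
            counts,
        )
        params = params.with_parameter(param)

    overrides = doc.get("settings") or {}
    bad = set(overrides) - _SETTINGS_KEYS
    if bad:
        raise ConfigError(f"unknown settings keys: {sorted(bad)}")
    if overrides:
        settings = replace(settings, **dict(overrides))

    return params, settings
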