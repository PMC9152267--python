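import math

import numpy as np
import pytest

from prophycea.parameters import (
    ConfigError,
    DistributionSpec,
    Parameter,
    ParameterSet,
    base_case_draw,
    default_parameters,
    draw_from_rng,
    dsa_bounds,
    export_parameters,
    fit_sampling_distribution,
    load_parameters,
    sample_parameter_set,
)

# printed input table: (name, base, low, high, family)
PUBLISHED_ROWS = [
    ("p_ifi_posaconazole", 0.046, 0.034, 0.058, "beta"),
    ("p_ifi_first_gen", 0.111, 0.083, 0.139, "beta"),
    ("p_death_ifi", 0.447, 0.335, 0.559, "beta"),
    ("p_death_other", 0.158, 0.119, 0.198, "beta"),
    ("surv5_aml", 0.44, 0.33, 0.55, "uniform"),
    ("surv5_mds", 0.52, 0.39, 0.65, "uniform"),
    ("cost_ifi_treatment", 5423.3, 4067.5, 6779.1, "uniform"),
    ("daily_cost_posa_susp", 45.56, 34.17, 56.95, "uniform"),
    ("daily_cost_posa_tab", 119.98, 89.99, 149.98, "uniform"),
    ("daily_cost_fluconazole", 0.26, 0.20, 0.33, "uniform"),
    ("daily_cost_itraconazole", 1.89, 1.42, 2.36, "uniform"),
    ("duration_posa", 29.0, 21.75, 36.25, "gamma"),
    ("duration_fluconazole", 24.0, 18.00, 30.00, "gamma"),
    ("duration_itraconazole", 29.0, 21.75, 36.25, "gamma"),
    ("discount_rate", 0.05, 0.0, 0.08, "uniform"),
    ("utility_induction", 0.648, 0.486, 0.810, "uniform"),
    ("utility_remission", 0.830, 0.623, 1.000, "uniform"),
]


@pytest.mark.parametrize("name,base,low,high,family", PUBLISHED_ROWS)
def test_defaults_match_published_table(params, name, base, low, high, family):
    p = params.get(name)
    assert p.spec.base == base
    assert p.spec.low == low
    assert p.spec.high == high
    assert p.spec.family == family
    # base-case value agrees with the printed base at printed precision
    # (counts-backed entries use the unrounded trial fraction)
    assert round(p.value, 3) == pytest.approx(base, abs=5e-4)


def test_counts_backed_values_are_unrounded_fractions(params):
    assert params.p_ifi_posaconazole.value == 14 / 304
    assert params.p_ifi_first_gen.value == 33 / 298
    assert params.p_death_ifi.value == 21 / 47


def test_probabilities_and_utilities_in_unit_interval(params):
    for p in params:
        if p.units in ("probability", "utility"):
            assert 0.0 <= p.value <= 1.0


def test_parameter_set_is_complete(params):
    assert len(list(params)) == len(ParameterSet.names()) == 17


@pytest.mark.parametrize(
    "name,expected",
    [
        ("utility_remission", (0.623, 1.000)),
        ("daily_cost_posa_susp", (34.17, 56.95)),
        ("discount_rate", (0.0, 0.08)),
    ],
)
def test_dsa_bounds_use_stated_range(params, name, expected):
    assert dsa_bounds(params.get(name)) == expected


def test_dsa_bounds_fallback_and_caps():
    zero = Parameter("x", "probability", DistributionSpec("beta", 0.0, 0.0, 0.0))
    assert dsa_bounds(zero) == (0.0, 0.0)
    cost = Parameter("c", "USD", DistributionSpec("uniform", 100.0, 100.0, 100.0))
    assert dsa_bounds(cost) == (75.0, 125.0)
    utility = Parameter("u", "utility", DistributionSpec("uniform", 0.9, 0.9, 0.9))
    assert dsa_bounds(utility) == (0.675, 1.0)  # +25% would exceed 1
    fixed = Parameter("f", "USD", DistributionSpec("fixed", 5.0, 5.0, 5.0))
    assert dsa_bounds(fixed) == (5.0, 5.0)


def test_moment_matching_round_trip(params):
    """Fitted beta/gamma mean = base and sd = range/3.92 to 1e-9."""
    for p in params:
        dist = fit_sampling_distribution(p)
        if p.spec.family in ("beta", "gamma"):
            assert dist.mean() == pytest.approx(p.spec.base, abs=1e-9)
            target_sd = (p.spec.high - p.spec.low) / 3.92
            assert dist.sd() == pytest.approx(target_sd, abs=1e-9)
        elif p.spec.family == "uniform":
            assert dist.mean() == pytest.approx(
                (p.spec.low + p.spec.high) / 2, abs=1e-12
            )


def test_fitted_beta_example(params):
    # method-of-moments oracle: k = m(1-m)/v - 1, alpha = m k, beta = (1-m) k
    m, v = 0.046, ((0.058 - 0.034) / 3.92) ** 2
    k = m * (1 - m) / v - 1
    dist = fit_sampling_distribution(params.p_ifi_posaconazole)
    assert dist.family == "beta"
    assert dist.a == pytest.approx(m * k, rel=1e-12)
    assert dist.b == pytest.approx((1 - m) * k, rel=1e-12)
    assert dist.a == pytest.approx(53.8, abs=0.1)
    assert dist.b == pytest.approx(1116.1, abs=0.5)


def test_fitted_gamma_example(params):
    v = ((36.25 - 21.75) / 3.92) ** 2
    dist = fit_sampling_distribution(params.duration_posa)
    assert dist.family == "gamma"
    assert dist.a == pytest.approx(29.0**2 / v, rel=1e-12)
    assert dist.b == pytest.approx(v / 29.0, rel=1e-12)
    assert dist.a == pytest.approx(61.5, abs=0.1)
    assert dist.b == pytest.approx(0.472, abs=0.001)


def test_fixed_family_is_degenerate():
    p = Parameter("f", "USD", DistributionSpec("fixed", 5.0, 5.0, 5.0))
    dist = fit_sampling_distribution(p)
    samples = dist.sample(np.random.default_rng(0), size=50)
    assert np.all(samples == 5.0)


def test_beta_fit_rejects_base_outside_unit_interval():
    p = Parameter("u", "utility", DistributionSpec("beta", 1.0, 0.9, 1.0))
    with pytest.raises(ValueError, match="beta"):
        fit_sampling_distribution(p)


def test_sampling_is_seed_deterministic(params):
    assert sample_parameter_set(params, 42) == sample_parameter_set(params, 42)
    assert sample_parameter_set(params, 42) != sample_parameter_set(params, 43)


def test_sample_means_match_analytic_means(params):
    """Monte-Carlo convergence: 10,000 joint draws, mean within 3 SE."""
    rng = np.random.default_rng(123)
    n = 10_000
    draws = {name: np.empty(n) for name in ParameterSet.names()}
    for i in range(n):
        for name, x in draw_from_rng(params, rng).items():
            draws[name][i] = x
    for p in params:
        dist = fit_sampling_distribution(p)
        if dist.sd() == 0.0:
            continue
        se = dist.sd() / math.sqrt(n)
        assert abs(draws[p.name].mean() - dist.mean()) < 3 * se, p.name
        if p.units in ("probability", "utility"):
            assert draws[p.name].min() >= 0.0
            assert draws[p.name].max() <= 1.0


def test_config_round_trip_is_identity(params, settings):
    text = export_parameters(params, settings)
    params2, settings2 = load_parameters(text)
    assert params2 == params
    assert settings2 == settings


def test_empty_override_equals_defaults():
    assert load_parameters({}) == default_parameters()
    assert load_parameters("") == default_parameters()


def test_single_field_override():
    params, settings = load_parameters(
        {"parameters": {"daily_cost_posa_susp": {"base": 30.0}}}
    )
    assert params.daily_cost_posa_susp.value == 30.0
    defaults, _ = default_parameters()
    assert params.p_ifi_posaconazole == defaults.p_ifi_posaconazole
    assert settings == default_parameters()[1]


def test_override_base_drops_stale_counts():
    """Setting the rounded base on a counts-backed row makes it effective."""
    params, _ = load_parameters(
        {"parameters": {"p_ifi_posaconazole": {"base": 0.046}}}
    )
    assert params.p_ifi_posaconazole.value == 0.046
    assert params.p_ifi_posaconazole.source_counts is None


@pytest.mark.parametrize(
    "doc,match",
    [
        ({"parameters": {"daily_cost_posa_susp": {"low": 0.9, "high": 0.1}}},
         "range error"),
        ({"parameters": {"daily_cost_posa_susp": {"family": "weibull"}}},
         "unknown distribution family"),
        ({"parameters": {"no_such_param": {"base": 1.0}}}, "unknown parameter"),
        ({"parameters": {"daily_cost_posa_susp": {}}}, "missing required"),
        ({"settings": {"no_such_setting": 3}}, "unknown settings"),
        ({"bogus_section": {}}, "unknown top-level"),
    ],
)
def test_invalid_configs_are_rejected(doc, match):
    with pytest.raises(ConfigError, match=match):
        load_parameters(doc)


def test_settings_override():
    _, settings = load_parameters({"settings": {"horizon_cycles": 1200,
                                                "fluconazole_share": 0.89}})
    assert settings.horizon_cycles == 1200
    assert settings.fluconazole_share == 0.89


def test_base_case_draw_uses_values(params):
    d = base_case_draw(params)
    assert d["p_ifi_posaconazole"] == 14 / 304
    assert d["daily_cost_posa_susp"] == 45.56
    assert set(d) == set(ParameterSet.names())
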