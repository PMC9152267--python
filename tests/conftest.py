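import pytest

from prophycea.decision_tree import builtin_strategies
from prophycea.parameters import base_case_draw, default_parameters
from prophycea.sensitivity import run_psa


@pytest.fixture(scope="session")
def model():
    return default_parameters()


@pytest.fixture()
def params(model):
    return model[0]


@pytest.fixture()
def settings(model):
    return model[1]


@pytest.fixture()
def draw(params):
    return base_case_draw(params)


@pytest.fixture()
def strategies(settings):
    return builtin_strategies(settings)


@pytest.fixture(scope="session")
def suspension_pair(model):
    """(reference, alternative) = (first-gen triazoles, posaconazole susp.)."""
    s = builtin_strategies(model[1])
    return (s["first_generation_triazoles"], s["posaconazole_suspension"])


@pytest.fixture(scope="session")
def psa_result(model, suspension_pair):
    """A moderate shared PSA run for distributional checks."""
    params, settings = model
    return run_psa(params, settings, suspension_pair, n_iterations=2000, seed=7)
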