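import pytest

from paraflux import (
    MediumSpec,
    toy_dual_pathway,
    toy_dual_substrate,
    toy_leaky,
    toy_linear,
    toy_respiratory,
)


@pytest.fixture
def linear_model():
    return toy_linear(200.0)


@pytest.fixture
def dual_pathway_model():
    return toy_dual_pathway()


@pytest.fixture
def respiratory_model():
    return toy_respiratory({"high_po": 10.0, "low_po": 6.0})


@pytest.fixture
def dual_substrate():
    """(model, oracle threshold) with the default parameterization."""
    return toy_dual_substrate()


@pytest.fixture
def leaky_model():
    return toy_leaky()


@pytest.fixture
def empty_medium():
    """No inorganic uptakes: enough for the fermentation-free linear toys."""
    return MediumSpec()


@pytest.fixture
def aerobic_medium(respiratory_model):
    return MediumSpec.inorganic(respiratory_model)
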