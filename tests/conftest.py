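import numpy as np
import pytest

from edflux import emu, synth
from edflux.model import split_reversible


@pytest.fixture(scope="session")
def models():
    """The shipped carbon and hydrogen ED-glycolysis models."""
    return synth.load_shipped_models()


@pytest.fixture(scope="session")
def split_models(models):
    return {el: split_reversible(m) for el, m in models.items()}


@pytest.fixture(scope="session")
def emunets(split_models):
    return {el: emu.decompose_emus(sm) for el, sm in split_models.items()}


@pytest.fixture(scope="session")
def n2_truth():
    return synth.make_truth("n2")


@pytest.fixture(scope="session")
def nh4_truth():
    return synth.make_truth("nh4")


@pytest.fixture(scope="session")
def n2_problem(models, n2_truth):
    """One noisy 4-tracer dataset from the N2 truth, shared across tests."""
    return synth.make_fit_problem(n2_truth, seed=11, models=models)


@pytest.fixture(scope="session")
def n2_fit(n2_problem):
    from edflux import fit

    return fit.fit_fluxes(n2_problem, n_starts=2, seed=12)


def assert_valid_mid(fractions, atol=1e-9):
    fractions = np.asarray(fractions)
    assert np.all(fractions >= -atol)
    assert abs(fractions.sum() - 1.0) < 1e-9
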