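import pytest

from youthprev import CalibrationTargets, PreventionModel

#: Published reference rates for the Australian youth population.
RATES = dict(i=0.03251, lam=0.07692, mu=0.0003343, alpha=1.0, beta=1.2, gamma=1.673)


@pytest.fixture(scope="session")
def targets():
    return CalibrationTargets()


@pytest.fixture(scope="session")
def table1_results():
    """Calibrated reference scenario (phi=0.4, theta=2, published rates)."""
    return PreventionModel(phi=0.4, theta=2.0, i=RATES["i"]).fit()


@pytest.fixture(scope="session")
def table1_params(table1_results):
    return table1_results.params
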