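import pytest

from crcscreen import default_parameters, run_arm


@pytest.fixture(scope="session")
def ng_params():
    return default_parameters("ng_mtsdna")


@pytest.fixture(scope="session")
def fit_params():
    return default_parameters("fit")


@pytest.fixture(scope="session")
def ng_result(ng_params):
    return run_arm(ng_params)


@pytest.fixture(scope="session")
def fit_result(fit_params):
    return run_arm(fit_params)
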