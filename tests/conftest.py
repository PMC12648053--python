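import pytest

from ckdcea import fixtures, scenarios


@pytest.fixture(scope="session")
def default_params():
    return fixtures.default_parameters()


@pytest.fixture(scope="session")
def base_result(default_params):
    return scenarios.run_base(default_params)
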