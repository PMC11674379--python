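import warnings

import pytest

from slncea import default_parameters, make_life_table


@pytest.fixture(scope="session")
def ps():
    return default_parameters()


@pytest.fixture(scope="session")
def lt():
    return make_life_table()


@pytest.fixture(autouse=True)
def _quiet_table_warnings():
    # the printed input table carries documented inconsistencies that warn
    # on every validation; keep test output readable
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*printed interval.*")
        warnings.filterwarnings("ignore", message=".*presumed a typo.*")
        warnings.filterwarnings("ignore", message=".*interval not used.*")
        yield
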