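import pytest

import imksurv as ik


@pytest.fixture(scope="session")
def table1():
    """Published HT1080 parameter set (packaged fixture)."""
    return ik.ht1080_table1()


@pytest.fixture(scope="session")
def published_design():
    return ik.published_design()


@pytest.fixture(scope="session")
def noisefree_data(table1, published_design):
    """The 37-condition design evaluated exactly (cv = 0)."""
    return ik.generate_survival_dataset(table1, published_design, ik.NoiseModel(cv=0.0, seed=1))
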