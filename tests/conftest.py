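import pandas as pd
import pytest

from rapbeef.fixtures import load_fixture


@pytest.fixture(scope="session")
def definitions():
    return load_fixture("table3")


@pytest.fixture(scope="session")
def table4():
    return load_fixture("table4")


@pytest.fixture(scope="session")
def farm_matrix(table4):
    return table4.score_matrix("farm")


@pytest.fixture(scope="session")
def slaughter_matrix(table4):
    return table4.score_matrix("slaughterhouse")


@pytest.fixture(scope="session")
def table7() -> pd.DataFrame:
    return load_fixture("table7")
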