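import pytest

from enpp1db.cohort import load_table1, load_table2
from enpp1db.gene_model import enpp1_model


@pytest.fixture(scope="session")
def patients():
    return load_table1()


@pytest.fixture(scope="session")
def variants():
    return load_table2()


@pytest.fixture(scope="session")
def model():
    return enpp1_model()
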