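import numpy as np
import pytest

from pearmedia.datasets import load_dataset
from pearmedia.bbd import load_paper_design


@pytest.fixture(scope="session")
def pyro_df():
    return load_dataset("Pyrodwarf")


@pytest.fixture(scope="session")
def ohf_df():
    return load_dataset("OHF")


@pytest.fixture(scope="session")
def design_df():
    return load_paper_design()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
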