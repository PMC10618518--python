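import numpy as np
import pytest
from hypothesis import settings

from taphonet import build_abundance_matrix
from taphonet.synthetic import worked_example, worked_example_reference

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def worked_table():
    """The deterministic 58-specimen, 4-plot, 8-OTU example table."""
    return worked_example()


@pytest.fixture(scope="session")
def worked_otu_matrix(worked_table):
    return build_abundance_matrix(worked_table, "otu")


@pytest.fixture(scope="session")
def worked_family_matrix(worked_table):
    return build_abundance_matrix(worked_table, "family")


@pytest.fixture(scope="session")
def worked_reference():
    return worked_example_reference()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
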