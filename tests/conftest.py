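import pytest

from strvalid import builtin_panel
from strvalid.cli_io import load_control_genotype
from strvalid.epg_sim import default_sim_params
from strvalid.popgen import synthetic_frequency_table


@pytest.fixture(scope="session")
def full_panel():
    return builtin_panel("full")


@pytest.fixture(scope="session")
def toy_panel():
    return builtin_panel("toy")


@pytest.fixture(scope="session")
def control_genotype():
    return load_control_genotype()


@pytest.fixture(scope="session")
def full_params(full_panel):
    return default_sim_params(full_panel)


@pytest.fixture(scope="session")
def full_freqs(full_panel):
    return synthetic_frequency_table(full_panel, seed=3)
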