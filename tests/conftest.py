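import pytest

from phagepan.germline import make_germline_set
from phagepan.simulate import PanningConfig, simulate_campaign, simulate_library


@pytest.fixture(scope="session")
def germline():
    return make_germline_set(20, 4, 4, seed=1)


@pytest.fixture(scope="session")
def small_campaign(germline):
    """300 clonotypes, 3,000 reads/round, 2 rounds — fast shared fixture."""
    cfg = PanningConfig(n_clonotypes=300, read_depth=3000, n_rounds=2, seed=11)
    truth, samples = simulate_campaign(cfg, germline)
    return cfg, truth, samples


@pytest.fixture(scope="session")
def small_library(germline):
    cfg = PanningConfig(n_clonotypes=200, read_depth=1000, seed=5)
    truth, sample = simulate_library(cfg, germline)
    return cfg, truth, sample
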