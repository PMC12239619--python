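import numpy as np
import pytest

from rcsim.founders import build_genetic_map, simulate_founder_panel
from rcsim.traits import TraitConfig, draw_architecture


@pytest.fixture(scope="session")
def small_map():
    return build_genetic_map(n_chromosomes=2, markers_per_chromosome=100, chromosome_length=1.6)


@pytest.fixture(scope="session")
def small_founders(small_map):
    return simulate_founder_panel(small_map, n_lines=60, target_heterozygosity=0.218, rng=11)


@pytest.fixture(scope="session")
def small_config():
    return TraitConfig(n_additive=40, n_dominant=40, n_qualitative=10, n_quantitative=10)


@pytest.fixture(scope="session")
def small_arch(small_map, small_config, small_founders):
    return draw_architecture(small_map, small_config, small_founders, rng=12, n_reference_crosses=400)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
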