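import numpy as np
import pytest

from lncscreen import build_default_library, SimConfig, simulate_screen
from lncscreen.simulate import make_truth


@pytest.fixture(scope="session")
def small_library():
    """12 lncRNA genes x 10 guides, 40 NTCs, 1 positive-control gene."""
    return build_default_library(
        n_lnc_genes=12, guides_per_gene=10, n_ntc=40, n_positive_genes=1, seed=11
    )


@pytest.fixture(scope="session")
def neutral_screen(small_library):
    """A fully neutral simulated screen over the small library."""
    cfg = SimConfig(seed=101, depth=200 * len(small_library))
    truth = make_truth(small_library, {}, cfg)
    table, _ = simulate_screen(small_library, truth, cfg)
    return table, truth, cfg


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
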