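import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from avirescue import synthetic_data as sd


@pytest.fixture(scope="session")
def small_sim():
    """One shared small synthetic run (30 genes, 3 species)."""
    cfg = sd.SimulationConfig(n_genes=30, n_species=3, seed=11)
    return sd.simulate_all(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
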