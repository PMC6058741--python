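import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from ervscan.synthetic import (SimulationConfig, make_reference_set,
                               plant_proviruses)

TEN_CLADE_TREE = ("(((HML1:0.10,HML2:0.12):0.05,(HML4:0.11,HML9:0.13):0.06):0.04,"
                  "((HML3:0.12,HML5:0.14):0.05,HML6:0.16):0.03,"
                  "((HML7:0.13,HML8:0.11):0.04,HML10:0.15):0.05);")


@pytest.fixture(scope="session")
def reference_library():
    """Ten clade-labeled reference coding sequences evolved along a known tree."""
    return make_reference_set(TEN_CLADE_TREE, rng_seed=101)


@pytest.fixture(scope="session")
def small_simulation(reference_library):
    """A 300 kb genome with 8 planted elements and its truth records."""
    config = SimulationConfig(
        genome_length=300_000, n_elements=8, substitution_rate=0.05,
        stop_probability=0.0, frameshift_probability=0.0,
        solo_ltr_probability=0.0,
        motifs=(("DTGAD", "GRDLL"), ("DTGVD", "GRDLL")),
        clades=("HML2", "HML3"), rng_seed=7)
    genome, truth, gff = plant_proviruses(config, reference_library)
    return config, genome, truth, gff


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
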