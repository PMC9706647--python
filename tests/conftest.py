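import numpy as np
import pandas as pd
import pytest

from chickscan import simdata
from chickscan.dataio import GenotypeDataset, TraitTable


@pytest.fixture()
def tiny_dataset():
    """4 samples x 3 markers, one missing call, two breeds in two types."""
    dosage = np.array(
        [
            [0.0, 1.0, 2.0],
            [1.0, np.nan, 2.0],
            [2.0, 0.0, 1.0],
            [0.0, 1.0, 0.0],
        ]
    )
    markers = pd.DataFrame(
        {
            "marker_id": ["m1", "m2", "m3"],
            "chromosome": ["1", "1", "2"],
            "position_bp": [100, 200, 50],
            "allele_a": ["A", "C", "G"],
            "allele_b": ["G", "T", "T"],
            "minor_allele": ["G", "T", "T"],
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "breed": ["b1", "b1", "b2", "b2"],
            "type": ["Game", "Game", "Bantam", "Bantam"],
            "sex": ["male", "female", "male", "female"],
        }
    )
    return GenotypeDataset(dosage, markers, samples)


@pytest.fixture(scope="session")
def small_sim():
    """A small default-config simulation shared across read-only tests."""
    cfg = simdata.SimulationConfig(n_markers=400, seed=11)
    return simdata.simulate(cfg)


@pytest.fixture(scope="session")
def panel_sim():
    """One study-shaped simulation (201 birds, 9 breeds, 5 traits)."""
    cfg = simdata.default_panel_config(seed=5, n_markers=2000)
    return cfg, simdata.simulate(cfg)

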