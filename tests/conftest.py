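import numpy as np
import pandas as pd
import pytest

from stepblup.pedigree import read_and_validate_pedigree
from stepblup.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def demo_sim():
    """One small simulated dataset shared by read-only tests."""
    cfg = SimulationConfig.demo(seed=1234)
    return simulate_dataset(cfg)


@pytest.fixture()
def trio_pedigree():
    """Sire (1), dam (2), offspring (3); listed offspring-first."""
    return read_and_validate_pedigree(
        pd.DataFrame({"id": [3, 1, 2], "sire": [1, 0, 0], "dam": [2, 0, 0]})
    )


@pytest.fixture()
def fullsib_mating_pedigree():
    """Two founders, two full sibs (3, 4), and their inbred offspring 5."""
    return read_and_validate_pedigree(
        pd.DataFrame(
            {
                "id": [1, 2, 3, 4, 5],
                "sire": [0, 0, 1, 1, 3],
                "dam": [0, 0, 2, 2, 4],
            }
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(987)
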