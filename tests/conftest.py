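import io

import numpy as np
import pytest

from evoregime.experiment import ExperimentConfig, generate_experiment
from evoregime.sync_io import PopulationManifest, read_sync


@pytest.fixture(scope="session")
def manifest23() -> PopulationManifest:
    return PopulationManifest.default_experiment()


@pytest.fixture()
def manifest2() -> PopulationManifest:
    from evoregime.sync_io import PopulationInfo

    return PopulationManifest([PopulationInfo("AS", "AS"), PopulationInfo("AC", "AC")])


@pytest.fixture()
def sync2(manifest2):
    text = "2R\t100\tA\t10:0:5:0:0:0\t0:0:0:0:0:0\n" "2R\t105\tA\t8:0:2:0:0:0\t5:0:5:0:1:0\n"
    return read_sync(io.StringIO(text), manifest2)


@pytest.fixture(scope="session")
def small_experiment():
    """A small planted-selection experiment shared across tests."""
    cfg = ExperimentConfig(n_sites=4000, seed=21)
    return generate_experiment(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
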