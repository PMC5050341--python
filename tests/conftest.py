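import numpy as np
import pytest

from inteinscan.block_models import load_packaged_models
from inteinscan.extein_context import load_reference_exteins
from inteinscan.synthetic_data import SimConfig, simulate_survey


@pytest.fixture(scope="session")
def splicing_models():
    return load_packaged_models("splicing")


@pytest.fixture(scope="session")
def hen_models():
    return load_packaged_models("hen")


@pytest.fixture(scope="session")
def all_models():
    return load_packaged_models("all")


@pytest.fixture(scope="session")
def model_map(all_models):
    return {m.name: m for m in all_models}


@pytest.fixture(scope="session")
def references():
    return load_reference_exteins()


@pytest.fixture(scope="session")
def small_survey():
    """A 20-genome survey with every genome intein-positive, moderate divergence."""
    cfg = SimConfig(seed=42, n_clusters=2, genomes_per_cluster=(10, 10),
                    intein_rate_per_cluster=(1.0, 1.0), divergence=0.1)
    return simulate_survey(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20160901)
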