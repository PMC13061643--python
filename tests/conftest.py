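import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import trimark as tm
from trimark import pipeline

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sim_config():
    return tm.SimConfig(seed=7, cells_per_type=200)


@pytest.fixture(scope="session")
def genome(sim_config):
    return tm.make_genome(sim_config)


@pytest.fixture(scope="session")
def hox_fixture(genome, sim_config):
    """Moderate-depth fixture shared across tests (200 cells)."""
    return tm.make_hox_fixture(genome, sim_config)


@pytest.fixture(scope="session")
def hox_tracks(hox_fixture):
    return pipeline.fixture_tracks(hox_fixture)


@pytest.fixture(scope="session")
def acceptance_fixture():
    """The reference study condition: 500 cells per modality, seed 42."""
    cfg = tm.SimConfig(seed=42, cells_per_type=500)
    genome = tm.make_genome(cfg)
    return genome, tm.make_hox_fixture(genome, cfg)


def make_fragments(records):
    """FragmentSet from (chrom, start, end, barcode, count) tuples."""
    return tm.FragmentSet(pd.DataFrame(
        records, columns=["chrom", "start", "end", "barcode", "count"]))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
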