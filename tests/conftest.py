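import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from taprna.config import PipelineConfig, SimulationConfig
from taprna.pipeline import run_pipeline
from taprna.synthetic_data import generate_dataset


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def dataset(sim_config):
    """Default synthetic dataset (promoter mutation rate 0.1)."""
    return generate_dataset(sim_config)


@pytest.fixture(scope="session")
def noiseless_dataset():
    return generate_dataset(SimulationConfig(seed=7,
                                             promoter_mutation_rate=0.0))


@pytest.fixture(scope="session")
def noiseless_run(noiseless_dataset):
    """Full pipeline on the noiseless fixture (exact promoter copies)."""
    ds = noiseless_dataset
    result = run_pipeline(
        ds.transcripts_h, ds.transcripts_m, ds.genome_h, ds.genome_m,
        {h: m for h, m, _ in ds.ortholog_pairs},
        config=PipelineConfig(), loops=ds.loops, tads=ds.tads)
    return ds, result


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture
def make_seq(rng):
    return lambda n, r=None: random_seq(r or rng, n)
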