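import numpy as np
import pytest

from cnvblock.config import human_config, macaque_config
from cnvblock.genome import Interval
from cnvblock.synthetic import (
    CohortConfig,
    NoiseModel,
    make_probe_set,
    random_cds,
    simulate_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20140827)


@pytest.fixture(scope="session")
def ancestral_cds():
    """A 64-codon coding sequence, the scale of a small defensin CDS."""
    return random_cds(64, np.random.default_rng(99))


def small_config(noise_sd=0.0, dropout=None, n_samples=8, seed=0):
    """A compact cohort for fast unit tests: 100-kb region, 20-kb block."""
    return CohortConfig(
        name="mini",
        region=Interval("chrT", 0, 100_000),
        mean_spacing=500.0,
        block=Interval("chrT", 40_000, 60_000),
        cn_range=(2, 6),
        n_samples=n_samples,
        noise=NoiseModel(sd=noise_sd, seed=seed),
        decoys=(),
        dropout=dropout,
    )


@pytest.fixture
def mini_cohort():
    """Noise-free compact cohort with its probes and truth."""
    config = small_config(noise_sd=0.0)
    probes = make_probe_set(config.region, config.mean_spacing, seed=1)
    matrix, truth = simulate_cohort(probes, config, rng=np.random.default_rng(2))
    return config, probes, matrix, truth


@pytest.fixture(scope="session")
def human_cfg():
    return human_config()


@pytest.fixture(scope="session")
def macaque_cfg():
    return macaque_config()
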