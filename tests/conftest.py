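import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from methmir import pipeline
from methmir.synthetic import SimulationConfig, simulate

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20110923)


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down study: same effect sizes, fewer genes/regions."""
    return SimulationConfig(n_genes=250, n_chromosomes=2, seed=11,
                            dmr_count=5, pmd_count=2, pmd_length=40000)


@pytest.fixture(scope="session")
def small_bundle(small_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("small_bundle")
    return simulate(small_config, out)


@pytest.fixture(scope="session")
def small_run(small_bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("small_run")
    return pipeline.run_all(small_bundle.out_dir, out)


@pytest.fixture(scope="session")
def big_config():
    """The default study conditions: 5000 genes, headline couplings."""
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def big_bundle(big_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("big_bundle")
    return simulate(big_config, out)


@pytest.fixture(scope="session")
def big_run(big_bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("big_run")
    return pipeline.run_all(big_bundle.out_dir, out)
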