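import numpy as np
import pytest
from hypothesis import settings

from parcgrad.synthgen import SynthConfig, make_cohort, make_mesh

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ring6():
    return make_mesh(6, "ring")


@pytest.fixture(scope="session")
def lattice36():
    return make_mesh(36, "lattice")


@pytest.fixture(scope="session")
def small_config():
    return SynthConfig(
        n_subjects=24,
        n_runs=2,
        T=80,
        n_vertices=36,
        K_group=6,
        n_latent=3,
        n_families=12,
        n_site_clusters=4,
        n_behaviors=3,
        topo_shift=2,
        effect_size=0.4,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return make_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
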