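import numpy as np
import pytest

from prommf.syncohort import SyntheticSpec, generate_cohort


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """A fast, low-dimensional cohort spec for unit tests."""
    return SyntheticSpec(
        n_patients=60,
        prevalence=0.3,
        n_genes=300,
        n_de_up=10,
        n_de_down=10,
        de_logfc=2.5,
        nb_dispersion=0.4,
        bag_size_range=(4, 10),
        informative_fraction=0.4,
        image_effect=3.0,
        signal_dim=8,
        embedding_dim=64,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
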