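import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import phenoprio as pp

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_instance():
    """Small planted-structure instance shared by evaluation tests."""
    cfg = pp.SynthConfig(
        n_genes=80,
        n_diseases=24,
        n_modules=4,
        module_pool_size=10,
        genes_per_disease=(1, 3),
        seed=7,
    )
    ppi, phenonet, dgmap = pp.generate(cfg)
    return cfg, ppi, phenonet, dgmap


@pytest.fixture(scope="session")
def calibrated_small(small_instance):
    """The small instance with its phenotype net normalized and calibrated."""
    _cfg, ppi, phenonet, dgmap = small_instance
    net = pp.logistic_transform(pp.normalize(phenonet, "tanimoto"), -15.0)
    return ppi, net, dgmap


def random_phenonet(rng, n=5, symmetric=False, scale=5.0):
    """Random positive matrix with dominant diagonal (helper, not a fixture)."""
    S = rng.uniform(0.1, scale, size=(n, n))
    if symmetric:
        S = (S + S.T) / 2.0
    S[np.diag_indices(n)] = S.max(axis=1) + rng.uniform(0.1, 1.0, size=n)
    return pp.PhenotypeNet([f"D{i}" for i in range(n)], S, symmetric=symmetric)
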