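import numpy as np
import pytest

import kld_dti as kd


@pytest.fixture(scope="session")
def three_class_collection():
    """Three well-separated classes, small enough for brute-force oracles."""
    specs = kd.default_specs(
        n_classes=3, n_ligands=20, conformers_per_ligand=3,
        n_bits=512, core_size=40,
    )
    return kd.generate_dataset(specs, seed=7)


@pytest.fixture(scope="session")
def beta_profiles():
    """Two skewed Beta-sample density profiles on the shared grid."""
    p = kd.estimate_density(kd.skewed_similarity_sample((2, 6), 5000, seed=1))
    q = kd.estimate_density(kd.skewed_similarity_sample((5, 2), 5000, seed=2))
    return p, q


def random_profile(rng, renormalize=True):
    """A density profile from a random Beta sample; helper for property tests."""
    a, b = rng.uniform(0.5, 8, size=2)
    values = rng.beta(a, b, size=500)
    return kd.estimate_density(values, renormalize=renormalize)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
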