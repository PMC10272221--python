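"""Shared fixtures: small thermally sampled chain datasets and trained models.

Session scope keeps the expensive sampling/training work shared across test
modules; all randomness is seeded, so fixtures are reproducible.
"""

import numpy as np
import pytest

from gdmlreduce.dataio import split_dataset
from gdmlreduce.descriptor import DescriptorSpec
from gdmlreduce.gdml import train
from gdmlreduce.simulate import build_toy_molecule, generate_dataset


@pytest.fixture(scope="session")
def chain8_topology():
    return build_toy_molecule("chain", 8, seed=11)


@pytest.fixture(scope="session")
def chain8_dataset(chain8_topology):
    return generate_dataset(chain8_topology, temperature=300.0,
                            n_samples=150, stride=10, dt=0.5, seed=11)


@pytest.fixture(scope="session")
def chain8_splits(chain8_dataset):
    return split_dataset(chain8_dataset, 30, 20, 60, seed=11)


@pytest.fixture(scope="session")
def chain8_spec():
    return DescriptorSpec.global_spec(8)


@pytest.fixture(scope="session")
def chain8_model(chain8_dataset, chain8_splits, chain8_spec):
    return train(chain8_dataset, chain8_splits.train, chain8_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_configuration(rng, n_atoms=5, spread=2.0):
    """Well-separated random geometry (no near-coincident atoms)."""
    from scipy.spatial.distance import pdist
    while True:
        coords = spread * rng.standard_normal((n_atoms, 3))
        if pdist(coords).min() > 0.5:
            return coords
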