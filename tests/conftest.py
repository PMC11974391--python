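"""Shared fixtures: tiny synthetic datasets, small models, rigid-motion
helpers. Everything is generated programmatically and seeded."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import foldembed as fe
from foldembed.synthetic import SyntheticSpec, generate_hierarchy


TINY_MODEL = fe.ModelConfig(
    hidden_dim=16,
    embedding_dim=8,
    n_layers=2,
    edge_hidden_dim=24,
    edge_out_dim=12,
    seed=7,
)


@pytest.fixture(scope="session")
def small_dataset():
    """16 families × 3 members with short chains; shared read-only."""
    spec = SyntheticSpec(members_per_family=3, length_range=(25, 45), seed=5)
    return generate_hierarchy(spec)


@pytest.fixture(scope="session")
def tiny_model():
    return fe.init_model(TINY_MODEL)


@pytest.fixture(scope="session")
def small_graphs(small_dataset):
    return [fe.featurize(item.structure) for item in small_dataset.domains[:12]]


def random_rigid_transform(coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Apply a uniformly random rotation plus a random translation."""
    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    shift = rng.uniform(-50.0, 50.0, size=3)
    return coords @ rot.as_matrix().T + shift


def make_structure(coords, name="toy") -> fe.DomainStructure:
    coords = np.asarray(coords, dtype=float)
    return fe.DomainStructure(
        name=name,
        ca_coords=coords,
        residue_numbers=np.arange(1, len(coords) + 1),
    )
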