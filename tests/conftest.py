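"""Shared fixtures: synthetic assemblies generated once per session."""

import numpy as np
import pytest

from hookjoint import (
    axial_distance_map,
    generate_straight,
    generate_supercoiled,
    index_lattice,
    native_spec,
    renumber_protofilaments,
    straight_spec,
)


@pytest.fixture(scope="session")
def straight26():
    spec = straight_spec(n_subunits=26)
    subunits, truth = generate_straight(spec)
    return subunits, truth


@pytest.fixture(scope="session")
def straight26_lattice(straight26):
    subunits, _ = straight26
    return index_lattice(subunits)


@pytest.fixture(scope="session")
def native26():
    """Supercoiled assembly at the native hook conditions
    (pitch 1290 Å, radius 165 Å, left-handed)."""
    spec = native_spec(n_subunits=26)
    subunits, truth = generate_supercoiled(spec)
    return subunits, truth


@pytest.fixture(scope="session")
def native26_lattice(native26):
    subunits, truth = native26
    lattice = index_lattice(subunits)
    profile = axial_distance_map(subunits, lattice, d0=truth.spec.d0)
    lattice = renumber_protofilaments(lattice, profile.per_protofilament_mean())
    return lattice


@pytest.fixture(scope="session")
def native26_profile(native26, native26_lattice):
    subunits, truth = native26
    return axial_distance_map(subunits, native26_lattice, d0=truth.spec.d0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20191122)
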