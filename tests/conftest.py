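import numpy as np
import pytest

from mmffkit import (
    EnergyOptions,
    FixtureSpec,
    atom_assignment,
    enumerate_interactions,
    generate_fixture,
    load_tables,
)


@pytest.fixture(scope="session")
def tables():
    return load_tables()


@pytest.fixture(scope="session")
def tables94s():
    return load_tables(variant="MMFF94s")


@pytest.fixture(scope="session")
def fixture_mol(tables):
    """Factory: cached fixture molecules by (name, seed, size)."""
    cache = {}

    def build(name, seed=3, size=4):
        key = (name, seed, size)
        if key not in cache:
            cache[key] = generate_fixture(FixtureSpec(name, seed=seed, size=size))
        return cache[key]

    return build


@pytest.fixture(scope="session")
def make_system(tables):
    """Factory: (molecule) -> (assignment, ForceFieldSystem)."""
    cache = {}

    def build(mol, options=None):
        key = (id(mol), repr(options))
        if key not in cache:
            assignment = atom_assignment(mol, tables)
            system = enumerate_interactions(
                mol, assignment, tables, options or EnergyOptions())
            cache[key] = (assignment, system)
        return cache[key]

    return build


def finite_difference_gradient(energy_fn, coords, h=1e-5):
    """Central finite differences of a scalar energy function."""
    coords = np.asarray(coords, dtype=float)
    g = np.zeros_like(coords)
    for i in range(coords.shape[0]):
        for c in range(3):
            cp = coords.copy()
            cp[i, c] += h
            cm = coords.copy()
            cm[i, c] -= h
            g[i, c] = (energy_fn(cp) - energy_fn(cm)) / (2.0 * h)
    return g
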