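"""Shared fixtures: reference parameters and small prepared systems.

Expensive prepared states (equilibrated or spread cells) are session-scoped
and seeded so every test sees the identical configuration.
"""

import numpy as np
import pytest

import semcell as sc
from semcell import scenarios

TEST_NP = 200          # scaled system: 180 cytoplasmic + 20 nuclear
SEED = 7


@pytest.fixture(scope="session")
def full_params():
    """Reference-table parameters at Np = 1000."""
    return sc.derive_pair_parameters(10.0, 1000, 0.74, 2.0, 2.0,
                                     1.2e-2, 5.0e-2, 0.75)


@pytest.fixture(scope="session")
def test_config():
    cfg = sc.load_config(overrides={"cell": {"Np": TEST_NP},
                                    "rng": {"seed": SEED}})
    return cfg


@pytest.fixture(scope="session")
def test_params(test_config):
    return sc.params_from_config(test_config)


@pytest.fixture(scope="session")
def test_table(test_config, test_params):
    return sc.table_from_config(test_config, test_params)


@pytest.fixture(scope="session")
def mixed_cell(test_config, test_params):
    """Randomly mixed 200-particle cell in a cylinder."""
    return sc.init_cell(TEST_NP, 0.10, radius=10.0, height=10.0,
                        min_spacing=0.5 * test_params.deq, seed=SEED,
                        mcell=3.1)


@pytest.fixture(scope="session")
def separated_cell(test_config, test_params, test_table, mixed_cell):
    """Phase-separated 200-particle cell (staged anneal, fixed seed)."""
    cell = mixed_cell.copy()
    drag = sc.drag_array(cell, test_params,
                         sc.nuclear_drag(test_config, test_params))
    cell, trace, reached = scenarios.equilibrate_nucleus(
        cell, test_table, test_params, drag, seed=SEED)
    assert reached
    return cell


@pytest.fixture(scope="session")
def spread_cell(test_config, test_params):
    """Synthetic pre-spread adherent cell at the LJ contact height."""
    sigma = test_config["ecm"]["sigma"]
    return scenarios.make_spread_cell(
        test_params, 0.10, z_bottom=2 ** (1 / 6) * sigma, seed=SEED)


def random_morse_system(n, params, seed=0, box=12.0):
    """Random single-kind configuration for force-oracle tests."""
    rng = np.random.default_rng(seed)
    positions = rng.uniform(-box / 2, box / 2, size=(n, 3))
    return sc.ParticleSystem(
        positions=positions,
        kinds=np.full(n, int(sc.ParticleKind.CYTOPLASM)),
        mobile=np.ones(n, dtype=bool),
        cell_id=np.zeros(n, dtype=np.int64))


def brute_force_forces(system, table):
    """O(N²) double-loop force oracle, independent of the neighbor list."""
    n = system.n
    forces = np.zeros((n, 3))
    for i in range(n):
        for j in range(i + 1, n):
            rij = system.positions[i] - system.positions[j]
            d = float(np.linalg.norm(rij))
            inter = table.get(system.kinds[i], system.kinds[j])
            if inter.form == "none":
                continue
            _, fmag = inter.energy_force(np.array([d]))
            fvec = fmag[0] / d * rij
            forces[i] += fvec
            forces[j] -= fvec
    return forces
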