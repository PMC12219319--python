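import numpy as np
import pytest

from nqeliq.forcefield import ForceField
from nqeliq.synthetic_data import ToyLiquidSpec, make_toy_liquid
from nqeliq.topology import AtomSpec, BondTerm, MolecularTopology, TetherTerm


@pytest.fixture(scope="session")
def toy_liquid():
    """A packed diatomic toy liquid (topology, positions, box)."""
    return make_toy_liquid(ToyLiquidSpec(), seed=42)


@pytest.fixture(scope="session")
def harmonic_diatomic():
    """Isolated harmonic diatomic, no nonbonded interactions."""
    top = MolecularTopology(
        atoms=[
            AtomSpec("X", 30.0, 0.0, sigma=1.0, epsilon=0.0),
            AtomSpec("H", 1.008, 0.0, sigma=1.0, epsilon=0.0),
        ],
        bonds=[BondTerm(0, 1, form="harmonic", k=3000.0, r0=0.95)],
    )
    pos = np.array([[0.0, 0.0, 0.0], [0.95, 0.0, 0.0]])
    return top, pos


def qho_topology(n_oscillators: int, k: float):
    """n free atoms each tethered harmonically to a distinct site."""
    atoms = [AtomSpec("H", 1.008, 0.0, 1.0, 0.0)] * n_oscillators
    tethers = [
        TetherTerm(i, k, x0=(10.0 * i, 0.0, 0.0)) for i in range(n_oscillators)
    ]
    return MolecularTopology(atoms=atoms, tethers=tethers)


@pytest.fixture(scope="session")
def qho_factory():
    return qho_topology


def block_sem(samples, n_blocks: int = 20) -> float:
    """SEM from block averages (robust to serial correlation)."""
    x = np.asarray(samples, dtype=float)
    m = len(x) // n_blocks
    blocks = x[: m * n_blocks].reshape(n_blocks, m).mean(axis=1)
    return float(blocks.std(ddof=1) / np.sqrt(n_blocks))


@pytest.fixture(scope="session")
def sem_of():
    return block_sem


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
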