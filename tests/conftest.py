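import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", module="MDAnalysis")

from mdtriage import (
    ContactPlant,
    SimSpec,
    make_toy_structure,
    simulate_trajectory,
)


@pytest.fixture(scope="session")
def toy_structure():
    """19-residue chain (pocket-sized) with a ligand, fixed seed."""
    return make_toy_structure(19, seed=11, ligand=True)


@pytest.fixture(scope="session")
def toy_protein():
    """Small ligand-free chain."""
    return make_toy_structure(8, seed=3, ligand=False)


@pytest.fixture()
def jitter_trajectory(toy_structure):
    """100 frames of isotropic jitter with one planted hydrogen bond."""
    spec = SimSpec(
        n_frames=100,
        seed=4,
        sigma=0.25,
        contact_schedule=[ContactPlant(6, "hbond", 0.6)],
    )
    return simulate_trajectory(toy_structure, spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
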