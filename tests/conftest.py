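import numpy as np
import pytest

from ddgcycle.structio import StructureModel, TopologyParams
from ddgcycle.synth import SynthSpec, make_complex


@pytest.fixture
def two_charges():
    """Two unit charges 1 Å apart — the Coulomb-constant sanity geometry."""
    s = StructureModel(
        ["A", "B"], ["H", "H"], np.array([0, 1]), ["IO1", "IO2"], ["A", "B"],
        np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]),
    )
    t = TopologyParams(
        charge=[1.0, 1.0], lj_rmin_half=[1.0, 1.0], lj_epsilon=[0.1, 0.1],
        mass=[1.0, 1.0], pb_radius=[1.0, 1.0],
        receptor_atoms=[0], ligand_atoms=[1],
    )
    return s, t


@pytest.fixture
def random_pair_system():
    """Seed-fixed 10-atom receptor / 5-atom ligand with random parameters."""
    rng = np.random.default_rng(42)
    n = 15
    coords = rng.uniform(-4.0, 4.0, size=(n, 3))
    # push apart any close contacts so LJ stays finite
    from scipy.spatial.distance import pdist

    while pdist(coords).min() < 1.5:
        coords = rng.uniform(-4.0, 4.0, size=(n, 3))
    s = StructureModel(
        [f"A{i}" for i in range(n)], ["C"] * n,
        np.array([0] * 10 + [1] * 5),
        ["REC"] * 10 + ["LIG"] * 5,
        ["R"] * 10 + ["L"] * 5,
        coords,
    )
    t = TopologyParams(
        charge=rng.uniform(-0.5, 0.5, n),
        lj_rmin_half=rng.uniform(1.2, 2.0, n),
        lj_epsilon=rng.uniform(0.05, 0.2, n),
        mass=rng.uniform(1.0, 16.0, n),
        pb_radius=rng.uniform(1.2, 2.0, n),
        receptor_atoms=np.arange(10),
        ligand_atoms=np.arange(10, 15),
    )
    return s, t


@pytest.fixture
def toy_complex():
    """Small deterministic synthetic complex shared across modules."""
    spec = SynthSpec(n_residues=4, ligand_atoms=4, n_frames=10, seed=7)
    s, t = make_complex(spec)
    return spec, s, t
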