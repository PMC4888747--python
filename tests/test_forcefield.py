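"""Gas-phase energies against closed forms and brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ddgcycle.constants import COULOMB_CONSTANT
from ddgcycle.forcefield import (
    CoincidentAtomError,
    bonded_energy,
    coulomb_interaction,
    lj_interaction,
    residue_decompose,
)
from ddgcycle.structio import StructureModel, TopologyParams


def brute_coulomb(coords, charge, ia, ib):
    """Independent double-loop summation (the oracle)."""
    e = 0.0
    for i in ia:
        for j in ib:
            r = np.sqrt(np.sum((coords[i] - coords[j]) ** 2))
            e += COULOMB_CONSTANT * charge[i] * charge[j] / r
    return e


def brute_lj(coords, rh, eps, ia, ib):
    e = 0.0
    for i in ia:
        for j in ib:
            r = np.sqrt(np.sum((coords[i] - coords[j]) ** 2))
            rm = rh[i] + rh[j]
            e_ij = np.sqrt(eps[i] * eps[j])
            e += e_ij * ((rm / r) ** 12 - 2 * (rm / r) ** 6)
    return e


def test_coulomb_unit_charges_at_1A(two_charges):
    s, t = two_charges
    assert coulomb_interaction(s, t, [0], [1]) == pytest.approx(COULOMB_CONSTANT)


def test_coulomb_closed_form_minus_100():
    s = StructureModel(["A", "B"], ["H", "H"], np.array([0, 1]), ["X", "Y"],
                       ["A", "B"], np.array([[0, 0, 0], [3.320637, 0, 0]], dtype=float))
    t = TopologyParams(charge=[1.0, -1.0], lj_rmin_half=[1, 1], lj_epsilon=[0, 0],
                       mass=[1, 1], pb_radius=[1, 1])
    assert coulomb_interaction(s, t, [0], [1]) == pytest.approx(-100.0)


def test_coulomb_matches_brute_force(random_pair_system):
    s, t = random_pair_system
    ia, ib = t.receptor_atoms, t.ligand_atoms
    assert coulomb_interaction(s, t, ia, ib) == pytest.approx(
        brute_coulomb(s.coords, t.charge, ia, ib), abs=1e-10
    )


def test_coulomb_rejects_overlapping_sets(random_pair_system):
    s, t = random_pair_system
    with pytest.raises(ValueError):
        coulomb_interaction(s, t, [0, 1], [1, 2])


def test_coulomb_coincident_atoms():
    s = StructureModel(["A", "B"], ["H", "H"], np.array([0, 1]), ["X", "Y"],
                       ["A", "B"], np.zeros((2, 3)))
    t = TopologyParams(charge=[1.0, 1.0], lj_rmin_half=[1, 1], lj_epsilon=[0, 0],
                       mass=[1, 1], pb_radius=[1, 1])
    with pytest.raises(CoincidentAtomError):
        coulomb_interaction(s, t, [0], [1])


@pytest.mark.parametrize(
    "r_over_rmin, expected_over_eps",
    [(1.0, -1.0), (2.0 ** (-1.0 / 6.0), 0.0)],
)
def test_lj_minimum_and_zero_crossing(r_over_rmin, expected_over_eps):
    rh = 1.6
    eps = 0.1
    r = r_over_rmin * 2 * rh
    s = StructureModel(["A", "B"], ["C", "C"], np.array([0, 1]), ["X", "Y"],
                       ["A", "B"], np.array([[0, 0, 0], [r, 0, 0]], dtype=float))
    t = TopologyParams(charge=[0, 0], lj_rmin_half=[rh, rh], lj_epsilon=[eps, eps],
                       mass=[1, 1], pb_radius=[1, 1])
    assert lj_interaction(s, t, [0], [1]) == pytest.approx(expected_over_eps * eps, abs=1e-12)


def test_lj_matches_brute_force(random_pair_system):
    s, t = random_pair_system
    ia, ib = t.receptor_atoms, t.ligand_atoms
    assert lj_interaction(s, t, ia, ib) == pytest.approx(
        brute_lj(s.coords, t.lj_rmin_half, t.lj_epsilon, ia, ib), abs=1e-10
    )


def test_interaction_symmetry(random_pair_system):
    s, t = random_pair_system
    ia, ib = t.receptor_atoms, t.ligand_atoms
    assert coulomb_interaction(s, t, ia, ib) == coulomb_interaction(s, t, ib, ia)
    assert lj_interaction(s, t, ia, ib) == lj_interaction(s, t, ib, ia)


def test_rigid_transform_invariance(random_pair_system):
    s, t = random_pair_system
    ia, ib = t.receptor_atoms, t.ligand_atoms
    rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.2]).as_matrix()
    moved = s.with_coords(s.coords @ rot.T + np.array([5.0, -3.0, 11.0]))
    assert abs(coulomb_interaction(moved, t, ia, ib)
               - coulomb_interaction(s, t, ia, ib)) < 1e-8
    assert abs(lj_interaction(moved, t, ia, ib) - lj_interaction(s, t, ia, ib)) < 1e-8
    assert abs(bonded_energy(moved, t) - bonded_energy(s, t)) < 1e-8


def test_bonded_energy_closed_forms():
    s = StructureModel(["A", "B"], ["C", "C"], np.array([0, 1]), ["X", "X"],
                       ["A", "A"], np.array([[0, 0, 0], [1.1, 0, 0]], dtype=float))
    t = TopologyParams(charge=[0, 0], lj_rmin_half=[1, 1], lj_epsilon=[0, 0],
                       mass=[1, 1], pb_radius=[1, 1], bonds=[(0, 1, 100.0, 1.0)])
    assert bonded_energy(s, t) == pytest.approx(100.0 * 0.1**2)  # k=100, dx=0.1
    at_r0 = s.with_coords(np.array([[0, 0, 0], [1.0, 0, 0]], dtype=float))
    assert bonded_energy(at_r0, t) == 0.0


def test_bonded_energy_chain_vs_direct_sum():
    rng = np.random.default_rng(5)
    n = 6
    coords = np.cumsum(rng.uniform(0.8, 1.4, size=(n, 3)), axis=0)
    bonds = [(i, i + 1, float(rng.uniform(50, 300)), float(rng.uniform(0.9, 1.3)))
             for i in range(n - 1)]
    s = StructureModel([f"A{i}" for i in range(n)], ["C"] * n, np.zeros(n, dtype=int),
                       ["CHN"] * n, ["A"] * n, coords)
    t = TopologyParams(charge=np.zeros(n), lj_rmin_half=np.ones(n),
                       lj_epsilon=np.zeros(n), mass=np.ones(n), pb_radius=np.ones(n),
                       bonds=bonds)
    expected = sum(k * (np.linalg.norm(coords[i] - coords[j]) - r0) ** 2
                   for i, j, k, r0 in bonds)
    assert bonded_energy(s, t) == pytest.approx(expected, abs=1e-10)


class TestResidueDecomposition:
    def test_single_residue_receptor_equals_total(self):
        rng = np.random.default_rng(11)
        coords = rng.uniform(-3, 3, size=(6, 3))
        coords[3:] += 8.0
        s = StructureModel([f"A{i}" for i in range(6)], ["C"] * 6,
                           np.array([0, 0, 0, 1, 1, 1]), ["REC"] * 3 + ["LIG"] * 3,
                           ["R"] * 3 + ["L"] * 3, coords)
        t = TopologyParams(charge=rng.uniform(-1, 1, 6), lj_rmin_half=np.full(6, 1.5),
                           lj_epsilon=np.full(6, 0.1), mass=np.ones(6),
                           pb_radius=np.ones(6), receptor_atoms=[0, 1, 2],
                           ligand_atoms=[3, 4, 5])
        br = residue_decompose(s, t)
        assert len(br.per_residue) == 1
        ele, vdw = br.per_residue[0]
        assert ele == pytest.approx(br.e_coulomb, abs=1e-10)
        assert vdw == pytest.approx(br.e_lj, abs=1e-10)

    def test_completeness_and_per_residue_oracle(self, random_pair_system):
        s, t = random_pair_system
        # split the 10 receptor atoms into 3 residues
        s.residue_index[:10] = [0, 0, 0, 1, 1, 1, 1, 2, 2, 2]
        s.residue_index[10:] = 3
        br = residue_decompose(s, t)
        total_ele = sum(v[0] for v in br.per_residue.values())
        total_vdw = sum(v[1] for v in br.per_residue.values())
        assert total_ele == pytest.approx(br.e_coulomb, abs=1e-8)
        assert total_vdw == pytest.approx(br.e_lj, abs=1e-8)
        for res, (ele, _) in br.per_residue.items():
            ia = np.flatnonzero(s.residue_index == res)
            ia = np.intersect1d(ia, t.receptor_atoms)
            assert ele == pytest.approx(
                brute_coulomb(s.coords, t.charge, ia, t.ligand_atoms), abs=1e-10)

    def test_decharged_residue_zero_ele(self, random_pair_system):
        s, t = random_pair_system
        s.residue_index[:10] = [0, 0, 0, 1, 1, 1, 1, 2, 2, 2]
        s.residue_index[10:] = 3
        t.charge[3:7] = 0.0  # residue 1
        br = residue_decompose(s, t)
        assert br.per_residue[1][0] == 0.0
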