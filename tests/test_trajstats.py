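"""RMSD/B-factor/contact-map/H-bond metrics against independent oracles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ddgcycle.structio import FrameEnsemble
from ddgcycle.synth import SynthSpec, make_complex, make_ensemble
from ddgcycle.trajstats import (
    bfactors,
    contact_map,
    cross_structure_rmsd,
    diff_map,
    hbond_series,
    superpose_rmsd,
)


def quaternion_rmsd(mobile, target):
    """Horn quaternion superposition (independent of the Kabsch path)."""
    mc, tc = mobile - mobile.mean(0), target - target.mean(0)
    m = mc.T @ tc
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    e0 = (mc**2).sum() + (tc**2).sum()
    msd = max(0.0, (e0 - 2.0 * lam) / len(mobile))
    return np.sqrt(msd)


@pytest.fixture(scope="module")
def ensemble():
    spec = SynthSpec(n_residues=4, ligand_atoms=4, n_frames=30, seed=17,
                     fluctuation_sigma=0.2)
    s, t = make_complex(spec)
    return s, t, make_ensemble(s, t, spec)


class TestRmsd:
    def test_identical_frames_zero(self, ensemble):
        s, t, _ = ensemble
        frames = FrameEnsemble(np.repeat(s.coords[None], 3, axis=0))
        assert np.allclose(superpose_rmsd(s, frames).values, 0.0, atol=1e-12)

    def test_rigid_copy_zero(self, ensemble):
        s, t, _ = ensemble
        rot = Rotation.from_euler("zyx", [1.0, -0.4, 2.5]).as_matrix()
        moved = s.coords @ rot.T + np.array([7.0, -2.0, 3.0])
        frames = FrameEnsemble(moved[None])
        assert superpose_rmsd(s, frames).values[0] < 1e-8

    def test_four_atom_pair_matches_quaternion_oracle(self):
        rng = np.random.default_rng(23)
        ref = rng.normal(size=(4, 3))
        frame = ref + rng.normal(0, 0.5, size=(4, 3))
        from ddgcycle.structio import StructureModel

        s = StructureModel(["A", "B", "C", "D"], ["C"] * 4, np.zeros(4, dtype=int),
                           ["X"] * 4, ["A"] * 4, ref)
        ours = superpose_rmsd(s, FrameEnsemble(frame[None])).values[0]
        assert ours == pytest.approx(quaternion_rmsd(frame, ref), abs=1e-10)

    def test_superposition_never_increases_rmsd(self, ensemble):
        s, t, ens = ensemble
        fitted = superpose_rmsd(s, ens).values
        raw = np.sqrt(np.mean(np.sum((ens.frames - s.coords) ** 2, axis=2), axis=1))
        assert np.all(fitted <= raw + 1e-12)

    def test_cross_structure_backbone_rmsd_excludes_side_chains(self, ensemble):
        s, t, _ = ensemble
        # perturb only side-chain atoms: backbone-matched RMSD stays zero
        coords = s.coords.copy()
        side = [i for i in range(s.n_atoms) if s.atom_names[i] == "CB"]
        coords[side] += 2.0
        assert cross_structure_rmsd(s, s.with_coords(coords)) < 1e-10


class TestBfactors:
    def test_zero_fluctuation(self, ensemble):
        s, t, _ = ensemble
        frames = FrameEnsemble(np.repeat(s.coords[None], 5, axis=0))
        assert np.allclose(bfactors(frames), 0.0, atol=1e-18)

    def test_single_frame_rejected(self, ensemble):
        s, t, _ = ensemble
        with pytest.raises(ValueError):
            bfactors(FrameEnsemble(s.coords[None]))

    def test_isotropic_noise_recovery(self):
        # B = 8 pi^2 sigma^2 for iid Gaussian displacement; superposition
        # removes 6 of 3N degrees of freedom, a (3N-6)/3N bias << tolerance
        # at this system size
        spec = SynthSpec(n_residues=40, ligand_atoms=6, n_frames=2000, seed=29,
                         fluctuation_sigma=0.25)
        s, t = make_complex(spec)
        ens = make_ensemble(s, t, spec)
        b = bfactors(ens)
        expected = 8.0 * np.pi**2 * spec.fluctuation_sigma**2
        assert b.mean() == pytest.approx(expected, rel=0.03)


class TestContactMap:
    def test_symmetric_zero_diagonal(self, ensemble):
        s, t, ens = ensemble
        cm = contact_map(s, ens)
        assert np.array_equal(cm.distances, cm.distances.T)
        assert np.allclose(np.diag(cm.distances), 0.0)

    def test_diff_of_identical_ensembles_zero(self, ensemble):
        s, t, ens = ensemble
        cm = contact_map(s, ens)
        assert np.allclose(diff_map(cm, cm).distances, 0.0)

    def test_three_residue_toy_matches_direct_average(self):
        rng = np.random.default_rng(31)
        from ddgcycle.structio import StructureModel

        coords = np.array([[0, 0, 0], [3, 0, 0], [0, 4, 0]], dtype=float)
        s = StructureModel(["CA"] * 3, ["C"] * 3, np.array([0, 1, 2]),
                           ["R"] * 3, ["A"] * 3, coords)
        frames = coords[None] + rng.normal(0, 0.3, size=(50, 3, 3))
        cm = contact_map(s, FrameEnsemble(frames))
        for i in range(3):
            for j in range(3):
                expected = np.mean(np.linalg.norm(frames[:, i] - frames[:, j], axis=1))
                assert cm.distances[i, j] == pytest.approx(expected, abs=1e-12)


class TestHbonds:
    def test_occupancy_limits(self):
        frames = np.zeros((20, 2, 3))
        frames[:, 1, 0] = 3.0
        assert hbond_series(FrameEnsemble(frames), [(0, 1)], cutoff=3.5).occupancy[0] == 1.0
        frames[:, 1, 0] = 7.0
        assert hbond_series(FrameEnsemble(frames), [(0, 1)], cutoff=3.5).occupancy[0] == 0.0

    def test_mean_distance_on_synthetic_pair(self):
        # iid Gaussian displacement of both partners: the mean separation is
        # the mean of a noncentral chi distribution; compare against a
        # large-sample Monte-Carlo of the same analytic model
        rng = np.random.default_rng(37)
        d0, sigma, n = 3.1, 0.2, 4000
        frames = np.zeros((n, 2, 3))
        frames[:, 1, 0] = d0
        frames += rng.normal(0, sigma, size=frames.shape)
        series = hbond_series(FrameEnsemble(frames), [(0, 1)], cutoff=3.5)
        sep_sigma = np.sqrt(2) * sigma
        oracle = rng.normal([d0, 0, 0], sep_sigma, size=(200000, 3))
        expected = np.linalg.norm(oracle, axis=1).mean()
        assert series.distances[:, 0].mean() == pytest.approx(expected, rel=0.01)
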