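"""Synthetic receptor–ligand systems with known ground truth.

Builds a desk-scale stand-in for a hydrogen-bonded binding pocket: a ring of
pseudo-residues (each with two neutral "backbone" atoms and one charged
"side-chain" atom pointing at the ligand) arcs around a small cyclic ligand
with alternating partial charges.  Two designated residues mimic a
serine/aspartate hydrogen-bonding pair, their side-chain charges placed
3.0–3.2 Å from complementary ligand charges.

"Alanine-like" mutants are made by side-chain charge annihilation (charges
zeroed, Lennard-Jones well depth reduced to a stub) with coordinates left
untouched, so the same pseudo-trajectory serves all four systems of a
double-mutant cycle.

Pseudo-trajectories are i.i.d. Gaussian displacements of the reference
(per-atom, per-axis sigma), drawn from numpy's seeded PCG64 generator —
bit-reproducible for a fixed spec.  A nonadditive three-body coupling of
known magnitude can be injected as an extra per-frame energy channel active
only while both designated side chains carry charge; downstream cycle
analysis must recover it with the opposite sign convention
(cooperativity = -c).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structio import FrameEnsemble, StructureModel, TopologyParams

__all__ = ["SynthSpec", "make_complex", "make_mutant", "make_ensemble",
           "designated_residues"]


@dataclass
class LJDefaults:
    rmin_half: float = 1.7  # Å
    epsilon: float = 0.1  # kcal/mol
    mass: float = 12.0  # amu
    pb_radius: float = 1.7  # Å


@dataclass
class SynthSpec:
    """Parameters of a synthetic complex and its pseudo-trajectory.

    Defaults mirror the binding-pocket statistics the analysis assumes:
    eight first-shell pseudo-residues, side-chain charges of a few tenths of
    an elementary charge, sub-Å positional fluctuations, and 800 snapshots
    for enthalpy averaging.
    """

    n_residues: int = 8
    atoms_per_residue: int = 3
    ligand_atoms: int = 6
    charge_scale: float = 0.4  # e, side-chain charge magnitude
    net_charge: float = 0.0  # e, total system charge
    lj_defaults: LJDefaults = field(default_factory=LJDefaults)
    fluctuation_sigma: float = 0.25  # Å per axis
    n_frames: int = 800
    coupling_constant: float = 0.0  # kcal/mol, three-body coupling magnitude
    coupling_noise_sigma: float = 0.3  # kcal/mol, per-frame channel noise
    drift_per_frame: float = 0.0  # Å, slow rigid translation per frame
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_residues, self.atoms_per_residue, self.ligand_atoms, self.n_frames) < 1:
            raise ValueError("all counts must be >= 1")
        if self.fluctuation_sigma < 0:
            raise ValueError("fluctuation_sigma must be >= 0")


def designated_residues(spec: SynthSpec) -> tuple[int, int]:
    """Residue indices of the two hydrogen-bonding (mutable) positions."""
    if spec.n_residues < 2:
        raise ValueError("need at least two residues for a double-mutant cycle")
    return 1, spec.n_residues - 2 if spec.n_residues > 2 else 0


def make_complex(spec: SynthSpec) -> tuple[StructureModel, TopologyParams]:
    """Deterministically build the reference complex and its parameters."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    lj = spec.lj_defaults
    names: list[str] = []
    elements: list[str] = []
    residx: list[int] = []
    resnames: list[str] = []
    chains: list[str] = []
    coords: list[np.ndarray] = []
    charge: list[float] = []

    # --- ligand: ring of alternating charges in the xy plane around origin
    lig_first = 0
    ring_r = 0.9
    for k in range(spec.ligand_atoms):
        ang = 2.0 * np.pi * k / spec.ligand_atoms
        coords.append(np.array([ring_r * np.cos(ang), ring_r * np.sin(ang), 0.0]))
        charge.append(0.35 * (1 if k % 2 else -1))
        names.append(f"L{k + 1}")
        elements.append("C")
        residx.append(0)
        resnames.append("LIG")
        chains.append("L")
    lig_idx = np.arange(lig_first, spec.ligand_atoms)

    hb_a, hb_b = designated_residues(spec)
    # ligand partner atoms for the designated residues: pick one negative
    # and one positive ligand charge
    partner = {hb_a: 0, hb_b: 1 if spec.ligand_atoms > 1 else 0}

    # --- receptor: pseudo-residues on a pocket-like arc
    arc_r = 6.0
    arc_span = np.deg2rad(240.0)
    rec_first = spec.ligand_atoms
    n_extra = max(0, spec.atoms_per_residue - 3)
    for r in range(spec.n_residues):
        ang = -arc_span / 2 + arc_span * (r + 0.5) / spec.n_residues
        u = np.array([np.cos(ang), np.sin(ang), 0.0])
        center = arc_r * u + np.array([0.0, 0.0, 0.35 * (-1) ** r])
        rid = r + 1
        resname = "SER" if r == hb_a else ("ASP" if r == hb_b else "GLN")
        # backbone: CA at the centre, N displaced outward
        for nm, pos in (("CA", center), ("N", center + 1.45 * u)):
            names.append(nm)
            elements.append(nm[0])
            residx.append(rid)
            resnames.append(resname)
            chains.append("R")
            coords.append(pos)
            charge.append(0.0)
        # side chain: one charged atom pointing at the ligand, carrying a
        # charge complementary to its nearest ligand atom so the pocket binds
        if r in partner:
            lig_at = coords[partner[r]]
            d = float(rng.uniform(3.0, 3.2))
            direction = (center - lig_at)
            direction /= np.linalg.norm(direction)
            sc_pos = lig_at + d * direction
            sc_charge = spec.charge_scale * (1 if charge[partner[r]] < 0 else -1)
        else:
            sc_pos = center - 2.0 * u
            dists = [float(np.linalg.norm(sc_pos - coords[k]))
                     for k in range(spec.ligand_atoms)]
            nearest = int(np.argmin(dists))
            sc_charge = spec.charge_scale * (1 if charge[nearest] < 0 else -1)
        names.append("CB")
        elements.append("C")
        residx.append(rid)
        resnames.append(resname)
        chains.append("R")
        coords.append(sc_pos)
        charge.append(sc_charge)
        for x in range(n_extra):
            names.append(f"X{x + 1}")
            elements.append("C")
            residx.append(rid)
            resnames.append(resname)
            chains.append("R")
            coords.append(center + np.array([0.0, 0.0, 1.4 * (x + 1)]))
            charge.append(0.0)

    coords_arr = np.array(coords)
    n = coords_arr.shape[0]
    charge_arr = np.array(charge)
    # neutralize the receptor exactly (correction over non-designated side
    # chains, falling back to all side chains) and put the declared net
    # charge on the ligand; backbones stay exactly neutral so annihilating a
    # side chain zeroes its whole residue, and a neutral receptor keeps the
    # far-field interaction monopole-free
    sc_atoms = [i for i in range(n)
                if names[i] == "CB" and chains[i] == "R"]
    atoms_per_res = 3 + n_extra
    designated_sc = {rec_first + r * atoms_per_res + 2 for r in partner}
    adjustable = [i for i in sc_atoms if i not in designated_sc] or sc_atoms
    rec_surplus = charge_arr[rec_first:].sum()
    charge_arr[adjustable] -= rec_surplus / len(adjustable)
    correction = (spec.net_charge - charge_arr.sum()) / spec.ligand_atoms
    charge_arr[lig_idx] += correction

    rec_idx = np.arange(rec_first, n)
    # bonds: ligand ring + residue internal (N-CA, CA-CB, CA-Xk chains),
    # equilibrium lengths at the built geometry so the reference is relaxed
    bonds: list[tuple[int, int, float, float]] = []

    def add_bond(i: int, j: int, k: float = 300.0) -> None:
        r0 = float(np.linalg.norm(coords_arr[i] - coords_arr[j]))
        bonds.append((i, j, k, r0))

    for k in range(spec.ligand_atoms):
        if spec.ligand_atoms > 1:
            add_bond(k, (k + 1) % spec.ligand_atoms)
    per_res = 2 + 1 + n_extra
    for r in range(spec.n_residues):
        base = rec_first + r * per_res
        add_bond(base, base + 1)  # CA-N
        add_bond(base, base + 2)  # CA-CB
        prev = base
        for x in range(n_extra):
            add_bond(prev, base + 3 + x)
            prev = base + 3 + x

    radius = np.full(n, lj.pb_radius)
    radius[lig_idx] = 1.5
    s = StructureModel(names, elements, np.array(residx), resnames, chains, coords_arr)
    t = TopologyParams(
        charge=charge_arr,
        lj_rmin_half=np.full(n, lj.rmin_half),
        lj_epsilon=np.full(n, lj.epsilon),
        mass=np.full(n, lj.mass),
        pb_radius=radius,
        bonds=bonds,
        receptor_atoms=rec_idx,
        ligand_atoms=lig_idx,
    )
    return s, t


#: Lennard-Jones well depth left on an annihilated side chain.
EPSILON_STUB = 0.01


def make_mutant(
    s: StructureModel,
    t: TopologyParams,
    residue: int,
) -> tuple[StructureModel, TopologyParams]:
    """Alanine-like mutant: annihilate one residue's side-chain charges.

    Side-chain atoms (everything except backbone N/CA) of ``residue`` have
    their partial charges zeroed and LJ epsilon reduced to a stub;
    coordinates are unchanged, so mutants share the wild-type geometry and
    the operation commutes — a double mutant is a mutant of a mutant in
    either order.
    """
    atoms = s.residue_atoms(residue)
    if atoms.size == 0:
        raise KeyError(f"no residue with index {residue}")
    side = [i for i in atoms if s.atom_names[i] not in ("N", "CA")]
    t2 = t.copy()
    t2.charge[side] = 0.0
    t2.lj_epsilon[side] = np.minimum(t2.lj_epsilon[side], EPSILON_STUB)
    s2 = StructureModel(
        list(s.atom_names), list(s.elements), s.residue_index.copy(),
        ["ALA" if i in set(int(a) for a in atoms) else rn
         for i, rn in enumerate(s.residue_names)],
        list(s.chain_ids), s.coords.copy(),
    )
    return s2, t2


def _sidechain_charged(s: StructureModel, t: TopologyParams, residue: int) -> bool:
    side = [i for i in s.residue_atoms(residue) if s.atom_names[i] not in ("N", "CA")]
    return bool(np.any(t.charge[side] != 0.0))


def make_ensemble(
    s: StructureModel,
    t: TopologyParams,
    spec: SynthSpec,
) -> FrameEnsemble:
    """Pseudo-trajectory: reference + i.i.d. Gaussian per-atom displacement.

    The coordinate stream depends only on ``spec.seed`` and the atom count,
    never on the charges, so wild type and mutants built from the same spec
    share bit-identical frames.  With a nonzero ``coupling_constant`` and
    both designated side chains charged, each frame records an extra
    favourable interaction ``-c`` (plus Gaussian channel noise) in
    ``extra_interaction``.
    """
    ss = np.random.SeedSequence(spec.seed)
    _, coord_seq, chan_seq = ss.spawn(3)
    rng = np.random.default_rng(coord_seq)
    n = s.n_atoms
    disp = rng.normal(0.0, spec.fluctuation_sigma, size=(spec.n_frames, n, 3)) \
        if spec.fluctuation_sigma > 0 else np.zeros((spec.n_frames, n, 3))
    frames = s.coords[None, :, :] + disp
    if spec.drift_per_frame:
        shift = spec.drift_per_frame * np.arange(spec.n_frames)
        frames = frames + shift[:, None, None] * np.array([1.0, 0.0, 0.0])
    extra = None
    if spec.coupling_constant != 0.0:
        hb_a, hb_b = designated_residues(spec)
        if _sidechain_charged(s, t, hb_a + 1) and _sidechain_charged(s, t, hb_b + 1):
            chan_rng = np.random.default_rng(chan_seq)
            extra = -spec.coupling_constant + chan_rng.normal(
                0.0, spec.coupling_noise_sigma, size=spec.n_frames
            )
    return FrameEnsemble(frames, extra_interaction=extra)
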