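"""Gas-phase molecular-mechanics energies.

Coulomb and 12-6 Lennard-Jones interaction energies between atom sets,
harmonic bond energies, and the per-residue decomposition of the
receptor–ligand interaction.  All energies in kcal/mol, no cutoff, vacuum
boundary — the convention for end-state (single-conformation) evaluation,
as opposed to the truncated/periodic schemes used by dynamics engines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .constants import COULOMB_CONSTANT
from .structio import StructureModel, TopologyParams

__all__ = [
    "GasEnergyBreakdown",
    "CoincidentAtomError",
    "coulomb_interaction",
    "lj_interaction",
    "bonded_energy",
    "residue_decompose",
]

#: Below this separation (Å) two atoms are considered coincident.
R_MIN_SANE = 1e-6


class CoincidentAtomError(ValueError):
    """Two interacting atoms are (numerically) on top of each other."""


@dataclass
class GasEnergyBreakdown:
    """Receptor–ligand gas-phase interaction, decomposed per receptor residue.

    ``per_residue`` maps residue index to its (electrostatic, van der Waals)
    contribution; the per-residue terms sum to the totals exactly (each
    atom pair is attributed to exactly one residue).
    """

    e_coulomb: float
    e_lj: float
    e_bonded: float = 0.0
    per_residue: dict[int, tuple[float, float]] = field(default_factory=dict)


def _as_index(atom_set) -> np.ndarray:
    idx = np.asarray(sorted(atom_set) if isinstance(atom_set, (set, frozenset)) else atom_set,
                     dtype=int)
    return idx


def _canonical_pair(ia: np.ndarray, ib: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Disjointness check plus a canonical ordering of the two sets, so the
    floating-point summation order — hence the result — is identical for
    (A, B) and (B, A)."""
    if np.intersect1d(ia, ib).size:
        raise ValueError("atom sets must be disjoint")
    if ib.size and (ia.size == 0 or (ib.size, tuple(ib)) < (ia.size, tuple(ia))):
        return ib, ia
    return ia, ib


def _pair_distances(coords: np.ndarray, ia: np.ndarray, ib: np.ndarray) -> np.ndarray:
    r = cdist(coords[ia], coords[ib])
    if r.size and r.min() < R_MIN_SANE:
        i, j = np.unravel_index(np.argmin(r), r.shape)
        raise CoincidentAtomError(
            f"atoms {ia[i]} and {ib[j]} are {r[i, j]:.2e} Å apart"
        )
    return r


def _coulomb(coords: np.ndarray, charge: np.ndarray, ia: np.ndarray, ib: np.ndarray,
             coulomb_constant: float = COULOMB_CONSTANT) -> float:
    if ia.size == 0 or ib.size == 0:
        return 0.0
    r = _pair_distances(coords, ia, ib)
    return float(coulomb_constant * np.sum(np.outer(charge[ia], charge[ib]) / r))


def _lj(coords: np.ndarray, rmin_half: np.ndarray, epsilon: np.ndarray,
        ia: np.ndarray, ib: np.ndarray) -> float:
    if ia.size == 0 or ib.size == 0:
        return 0.0
    r = _pair_distances(coords, ia, ib)
    rmin = np.add.outer(rmin_half[ia], rmin_half[ib])
    eps = np.sqrt(np.outer(epsilon[ia], epsilon[ib]))
    s6 = (rmin / r) ** 6
    return float(np.sum(eps * (s6 * s6 - 2.0 * s6)))


def coulomb_interaction(
    s: StructureModel,
    t: TopologyParams,
    set_a,
    set_b,
    coulomb_constant: float = COULOMB_CONSTANT,
) -> float:
    """Coulomb interaction energy (kcal/mol) between two disjoint atom sets.

    ``sum_{i in A, j in B} f q_i q_j / r_ij`` with
    ``f = 332.0637 kcal·Å/(mol·e²)`` by default; no cutoff, no periodicity.
    """
    ia, ib = _canonical_pair(_as_index(set_a), _as_index(set_b))
    return _coulomb(s.coords, t.charge, ia, ib, coulomb_constant)


def lj_interaction(s: StructureModel, t: TopologyParams, set_a, set_b) -> float:
    """12-6 Lennard-Jones interaction energy (kcal/mol) between disjoint sets.

    ``eps_ij [(rmin_ij/r)^12 - 2 (rmin_ij/r)^6]`` with Lorentz–Berthelot
    combination: ``rmin_ij = rmin_half_i + rmin_half_j``,
    ``eps_ij = sqrt(eps_i eps_j)``.
    """
    ia, ib = _canonical_pair(_as_index(set_a), _as_index(set_b))
    return _lj(s.coords, t.lj_rmin_half, t.lj_epsilon, ia, ib)


def bonded_energy(s: StructureModel, t: TopologyParams, atom_set=None) -> float:
    """Harmonic bond energy ``sum k (r - r0)^2`` over bonds inside ``atom_set``.

    With ``atom_set=None`` all bonds are summed.  A bond contributes only if
    both its atoms belong to the set.
    """
    if not t.bonds:
        return 0.0
    members = None if atom_set is None else set(int(i) for i in _as_index(atom_set))
    e = 0.0
    for i, j, k, r0 in t.bonds:
        if members is not None and (i not in members or j not in members):
            continue
        r = float(np.linalg.norm(s.coords[i] - s.coords[j]))
        e += k * (r - r0) ** 2
    return e


def residue_decompose(s: StructureModel, t: TopologyParams) -> GasEnergyBreakdown:
    """Attribute the receptor–ligand interaction to receptor residues.

    Each receptor residue receives the Coulomb and Lennard-Jones pair terms
    between its own atoms and the ligand; summing over residues recovers the
    total interaction exactly.
    """
    ir, il = _as_index(t.receptor_atoms), _as_index(t.ligand_atoms)
    per_residue: dict[int, tuple[float, float]] = {}
    total_ele = 0.0
    total_vdw = 0.0
    for res in np.unique(s.residue_index[ir]):
        ires = ir[s.residue_index[ir] == res]
        ele = _coulomb(s.coords, t.charge, ires, il)
        vdw = _lj(s.coords, t.lj_rmin_half, t.lj_epsilon, ires, il)
        per_residue[int(res)] = (ele, vdw)
        total_ele += ele
        total_vdw += vdw
    return GasEnergyBreakdown(
        e_coulomb=total_ele,
        e_lj=total_vdw,
        e_bonded=bonded_energy(s, t),
        per_residue=per_residue,
    )
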