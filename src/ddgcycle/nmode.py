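"""Harmonic (normal-mode) entropy of a conformation.

Pipeline: minimize the structure under the module potential (harmonic bonds
plus intramolecular Coulomb and Lennard-Jones, 1-2 bonded pairs excluded),
build a mass-weighted finite-difference Hessian, project out the rigid-body
translations and rotations, convert the remaining eigenvalues to harmonic
frequencies, and evaluate vibrational entropy together with ideal-gas
translational (Sackur–Tetrode) and rigid-rotor rotational terms.

Entropies are in cal/(mol·K); the binding-relevant quantity ``-T*dS`` is in
kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .constants import (
    AMU_KG,
    C2_CM_K,
    C_LIGHT_CM,
    COULOMB_CONSTANT,
    EIGVAL_TO_OMEGA_SQ,
    H_PLANCK,
    KB_SI,
    P_STANDARD,
    R_CAL,
    T_DEFAULT,
)
from .structio import StructureModel, TopologyParams

__all__ = [
    "EntropyResult",
    "MinimizationError",
    "ImaginaryFrequencyError",
    "minimize",
    "hessian",
    "entropy",
    "binding_minus_t_ds",
]

#: Modes with |frequency| below this (cm⁻¹) are treated as numerical zeros.
FREQUENCY_FLOOR = 0.5

#: Default gradient-norm convergence threshold, kcal/(mol·Å).
GRAD_TOL = 1.0e-4


class MinimizationError(RuntimeError):
    """Geometry optimization did not reach the requested gradient norm."""


class ImaginaryFrequencyError(ValueError):
    """The Hessian has negative curvature beyond the numerical floor."""


@dataclass
class EntropyResult:
    """Harmonic entropy decomposition of one conformation."""

    s_vib: float  # cal/(mol·K)
    s_trans: float
    s_rot: float
    s_total: float
    minus_T_dS: float  # kcal/mol, -T * s_total
    frequencies: np.ndarray  # cm⁻¹, sorted ascending
    n_projected_modes: int
    n_floored_modes: int = 0
    temperature: float = T_DEFAULT
    _extra: dict = field(default_factory=dict)


def _atoms(atom_set, n: int) -> np.ndarray:
    if atom_set is None:
        return np.arange(n)
    return np.asarray(sorted(atom_set) if isinstance(atom_set, (set, frozenset)) else atom_set,
                      dtype=int)


class _Potential:
    """Bonded + intramolecular nonbonded potential over an atom subset.

    Nonbonded pairs directly joined by a bond (1-2) are excluded; all other
    intra-set pairs interact with full Coulomb and Lennard-Jones terms.
    """

    def __init__(self, t: TopologyParams, sel: np.ndarray):
        self.sel = sel
        pos = {int(a): k for k, a in enumerate(sel)}
        self.bonds = [
            (pos[i], pos[j], k, r0)
            for i, j, k, r0 in t.bonds
            if i in pos and j in pos
        ]
        n = sel.size
        bonded = set((min(a, b), max(a, b)) for a, b, _, _ in self.bonds)
        pairs = [
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if (i, j) not in bonded
        ]
        self.pi = np.array([p[0] for p in pairs], dtype=int)
        self.pj = np.array([p[1] for p in pairs], dtype=int)
        q = t.charge[sel]
        self.qq = COULOMB_CONSTANT * q[self.pi] * q[self.pj]
        rh = t.lj_rmin_half[sel]
        ep = t.lj_epsilon[sel]
        self.rmin = rh[self.pi] + rh[self.pj]
        self.eps = np.sqrt(ep[self.pi] * ep[self.pj])
        self.mass = t.mass[sel]

    def energy_gradient(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        xyz = x.reshape(-1, 3)
        g = np.zeros_like(xyz)
        e = 0.0
        for i, j, k, r0 in self.bonds:
            d = xyz[i] - xyz[j]
            r = np.linalg.norm(d)
            e += k * (r - r0) ** 2
            f = 2.0 * k * (r - r0) / max(r, 1e-12) * d
            g[i] += f
            g[j] -= f
        if self.pi.size:
            d = xyz[self.pi] - xyz[self.pj]
            r2 = np.einsum("ij,ij->i", d, d)
            r = np.sqrt(r2)
            e_c = self.qq / r
            s6 = (self.rmin / r) ** 6
            e_lj = self.eps * (s6 * s6 - 2.0 * s6)
            e += float(e_c.sum() + e_lj.sum())
            # dE/dr terms
            de = -e_c / r + self.eps * (-12.0 * s6 * s6 + 12.0 * s6) / r
            f = (de / r)[:, None] * d
            np.add.at(g, self.pi, f)
            np.add.at(g, self.pj, -f)
        return e, g.ravel()


def minimize(
    s: StructureModel,
    t: TopologyParams,
    atom_set=None,
    tol: float = GRAD_TOL,
    max_iter: int = 5000,
) -> StructureModel:
    """Minimize the structure until the RMS gradient is below ``tol``.

    Only the atoms in ``atom_set`` move (default: all); the rest of the
    structure is returned unchanged.
    """
    sel = _atoms(atom_set, s.n_atoms)
    pot = _Potential(t, sel)
    x0 = s.coords[sel].ravel()

    res = _scipy_minimize(
        pot.energy_gradient, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": 1e-12, "ftol": 1e-15},
    )
    x = res.x
    _, g = pot.energy_gradient(x)
    rms = float(np.sqrt(np.mean(g * g)))
    if rms > tol:
        raise MinimizationError(
            f"RMS gradient {rms:.3e} kcal/(mol·Å) above tolerance {tol:.3e} "
            f"after {res.nit} iterations"
        )
    coords = s.coords.copy()
    coords[sel] = x.reshape(-1, 3)
    return s.with_coords(coords)


def hessian(
    s: StructureModel,
    t: TopologyParams,
    atom_set=None,
    step: float = 1.0e-4,
) -> np.ndarray:
    """Central-difference Hessian (3N x 3N, kcal/mol/Å²), symmetrized."""
    sel = _atoms(atom_set, s.n_atoms)
    pot = _Potential(t, sel)
    x = s.coords[sel].ravel().copy()
    n = x.size
    h = np.empty((n, n))
    for k in range(n):
        x[k] += step
        _, gp = pot.energy_gradient(x)
        x[k] -= 2.0 * step
        _, gm = pot.energy_gradient(x)
        x[k] += step
        h[k] = (gp - gm) / (2.0 * step)
    return 0.5 * (h + h.T)


def _rigid_body_vectors(coords: np.ndarray, mass: np.ndarray, linear: bool) -> np.ndarray:
    """Orthonormal mass-weighted translation/rotation vectors (columns)."""
    n = coords.shape[0]
    com = np.average(coords, axis=0, weights=mass)
    x = coords - com
    sm = np.sqrt(mass)
    vecs = []
    for ax in range(3):
        v = np.zeros((n, 3))
        v[:, ax] = sm
        vecs.append(v.ravel())
    axes = np.eye(3)
    for ax in axes:
        v = np.cross(x, ax) * sm[:, None]
        vecs.append(v.ravel())
    V = np.column_stack(vecs)
    # orthonormalize, dropping linearly dependent rotations (linear species)
    qmat, rmat = np.linalg.qr(V)
    keep = np.abs(np.diag(rmat)) > 1e-8
    qmat = qmat[:, keep]
    expected = 5 if linear else 6
    return qmat[:, :expected] if qmat.shape[1] >= expected else qmat


def _is_linear(coords: np.ndarray, mass: np.ndarray) -> bool:
    com = np.average(coords, axis=0, weights=mass)
    x = coords - com
    inertia = np.einsum("i,ij,ik->jk", mass, x, x)
    I = np.trace(inertia) * np.eye(3) - inertia
    ev = np.sort(np.linalg.eigvalsh(I))
    return ev[0] < 1e-8 * max(ev[2], 1e-12)


def frequencies_cm(
    s: StructureModel,
    t: TopologyParams,
    atom_set=None,
) -> tuple[np.ndarray, int]:
    """Harmonic frequencies (cm⁻¹, signed: negative = imaginary) after
    rigid-body projection.  Returns ``(frequencies, n_projected)``."""
    sel = _atoms(atom_set, s.n_atoms)
    H = hessian(s, t, sel)
    m = t.mass[sel]
    sm = np.repeat(np.sqrt(m), 3)
    Hmw = H / np.outer(sm, sm)
    coords = s.coords[sel]
    linear = _is_linear(coords, m)
    V = _rigid_body_vectors(coords, m, linear)
    P = np.eye(Hmw.shape[0]) - V @ V.T
    Hp = P @ Hmw @ P
    lam = np.linalg.eigvalsh(0.5 * (Hp + Hp.T))
    # drop the projected rigid-body null space (smallest |lambda| modes)
    n_proj = V.shape[1]
    order = np.argsort(np.abs(lam))
    lam_vib = np.sort(lam[order[n_proj:]])
    nu = np.sign(lam_vib) * np.sqrt(np.abs(lam_vib) * EIGVAL_TO_OMEGA_SQ) / (
        2.0 * np.pi * C_LIGHT_CM
    )
    return nu, n_proj


def _s_vib_mode(nu_cm: np.ndarray, T: float) -> np.ndarray:
    x = C2_CM_K * nu_cm / T
    return R_CAL * (x / np.expm1(x) - np.log1p(-np.exp(-x)))


def entropy(
    s: StructureModel,
    t: TopologyParams,
    atom_set=None,
    temperature: float = T_DEFAULT,
    frequency_floor: float = FREQUENCY_FLOOR,
) -> EntropyResult:
    """Harmonic entropy of a (minimized) conformation.

    Vibrational entropy sums the harmonic-oscillator expression over all
    real modes above ``frequency_floor``; translation uses Sackur–Tetrode at
    1 atm; rotation the classical rigid rotor over the principal moments.
    Raises :class:`ImaginaryFrequencyError` if negative curvature beyond the
    floor remains — the structure must be minimized first.
    """
    sel = _atoms(atom_set, s.n_atoms)
    nu, n_proj = frequencies_cm(s, t, sel)
    bad = np.flatnonzero(nu < -frequency_floor)
    if bad.size:
        raise ImaginaryFrequencyError(
            f"imaginary frequencies {nu[bad].round(2).tolist()} cm⁻¹; "
            "minimize the structure before the entropy evaluation"
        )
    floored = int(np.sum(np.abs(nu) < frequency_floor))
    real = nu[nu >= frequency_floor]
    s_vib = float(_s_vib_mode(real, temperature).sum()) if real.size else 0.0

    m = t.mass[sel]
    total_mass_kg = m.sum() * AMU_KG
    kT = KB_SI * temperature
    q_t = (2.0 * np.pi * total_mass_kg * kT / H_PLANCK**2) ** 1.5 * kT / P_STANDARD
    s_trans = R_CAL * (np.log(q_t) + 2.5)

    coords = s.coords[sel]
    com = np.average(coords, axis=0, weights=m)
    x = coords - com
    inertia = np.einsum("i,ij,ik->jk", m, x, x)
    I3 = (np.trace(inertia) * np.eye(3) - inertia) * AMU_KG * 1e-20  # kg·m²
    ev = np.sort(np.linalg.eigvalsh(I3))
    rot_const = 8.0 * np.pi**2 * kT / H_PLANCK**2
    if sel.size == 1:
        s_rot = 0.0
    elif _is_linear(coords, m):
        q_r = 8.0 * np.pi**2 * ev[2] * kT / H_PLANCK**2
        s_rot = R_CAL * (np.log(q_r) + 1.0)
    else:
        q_r = np.sqrt(np.pi * np.prod(rot_const * ev))
        s_rot = R_CAL * (np.log(q_r) + 1.5)

    s_total = s_vib + s_trans + s_rot
    return EntropyResult(
        s_vib=s_vib,
        s_trans=float(s_trans),
        s_rot=float(s_rot),
        s_total=float(s_total),
        minus_T_dS=float(-temperature * s_total / 1000.0),
        frequencies=np.sort(nu),
        n_projected_modes=n_proj,
        n_floored_modes=floored,
        temperature=temperature,
    )


def binding_minus_t_ds(
    s: StructureModel,
    t: TopologyParams,
    temperature: float = T_DEFAULT,
    tol: float = GRAD_TOL,
) -> float:
    """Binding entropy penalty ``-T dS_bind`` (kcal/mol) of a complex.

    The complex, receptor and ligand are each minimized in vacuum under the
    module potential and their harmonic entropies differenced:
    ``-T (S_complex - S_receptor - S_ligand)``.  Positive values mean
    entropy is lost on binding.
    """
    parts = {}
    for name, sel in (
        ("complex", np.concatenate([t.receptor_atoms, t.ligand_atoms])),
        ("receptor", t.receptor_atoms),
        ("ligand", t.ligand_atoms),
    ):
        mini = minimize(s, t, sel, tol=tol)
        parts[name] = entropy(mini, t, sel, temperature=temperature)
    return parts["complex"].minus_T_dS - parts["receptor"].minus_T_dS - parts["ligand"].minus_T_dS
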