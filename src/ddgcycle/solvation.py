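"""Implicit-solvent energies: Poisson–Boltzmann, generalized Born, SASA.

Polar solvation is computed by a finite-difference solve of the linearized
Poisson(-Boltzmann) equation on a regular grid.  The vacuum reference is
solved on the *identical* grid with the exterior dielectric set to 1, so the
grid self-energy of the spread charges cancels in the difference:

    dG_pol = 1/2 sum_i q_i (phi_solvated(r_i) - phi_vacuum(r_i))

A pairwise generalized-Born evaluation (Still functional form, effective
radii from the Coulomb-field approximation over the van der Waals volume)
provides a grid-free fast path used for per-frame analysis and as a
consistency check against the grid solver.

Nonpolar solvation is the standard linear SASA model ``G_np = gamma*A + b``;
surface areas come from an in-repo sphere-point (Shrake–Rupley style)
algorithm with a deterministic Fibonacci point set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial.distance import cdist

from .constants import COULOMB_CONSTANT, KB_KCAL, N_AVOGADRO
from .structio import StructureModel, TopologyParams

__all__ = [
    "PBSettings",
    "NonpolarModel",
    "SolverError",
    "ResolutionError",
    "pb_polar_energy",
    "gb_polar_energy",
    "gb_polar_energy_per_atom",
    "sasa",
    "nonpolar_energy",
]


class SolverError(RuntimeError):
    """The iterative PB solve failed to reach the requested residual."""


class ResolutionError(MemoryError):
    """The requested grid would exceed the configured memory budget."""


@dataclass
class PBSettings:
    """Finite-difference Poisson–Boltzmann solver settings.

    ``eps_in``/``eps_out`` are the solute/solvent dielectric constants
    (1 and 80 by default), ``grid_spacing`` the lattice constant in Å,
    ``grid_padding`` the margin added around the solute.  The boundary
    potential is either zero or a Debye–Hückel monopole sum at the grid
    faces.  The dielectric surface is the van der Waals surface of the
    intrinsic-radius spheres by default; ``"SES"`` approximates a
    solvent-excluded surface by inflating the radii by the probe radius.
    """

    eps_in: float = 1.0
    eps_out: float = 80.0
    grid_spacing: float = 0.5  # Å
    grid_padding: float = 10.0  # Å
    ionic_strength: float = 0.0  # mol/L
    boundary_condition: str = "debye-hueckel"  # or "zero"
    surface_def: str = "vdW"  # or "SES"
    probe_radius: float = 1.4  # Å, used only for surface_def="SES"
    temperature: float = 300.0  # K, enters the Debye screening length
    rtol: float = 1e-8  # relative residual for the linear solve
    max_iter: int = 20000
    max_grid_points: int = 6_000_000

    def __post_init__(self) -> None:
        if not (self.eps_out >= self.eps_in >= 1.0):
            raise ValueError("require eps_out >= eps_in >= 1")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be > 0")

    def kappa(self) -> float:
        """Inverse Debye length in Å⁻¹ for the configured ionic strength."""
        if self.ionic_strength <= 0:
            return 0.0
        # kappa^2 = 8 pi l_B n_I for a 1:1 electrolyte; l_B in Å,
        # n_I = I * N_A / 1e27 per Å^3.
        l_b = COULOMB_CONSTANT / (self.eps_out * KB_KCAL * self.temperature)
        n = self.ionic_strength * N_AVOGADRO / 1e27
        return float(np.sqrt(8.0 * np.pi * l_b * n))


@dataclass
class NonpolarModel:
    """Linear SASA nonpolar solvation model ``G_np = gamma*A_s + b``.

    Defaults: gamma = 0.00542 kcal/(mol·Å²), b = 0.92 kcal/mol, probe
    radius 1.4 Å, 960 sphere points per atom.
    """

    gamma: float = 0.00542  # kcal/(mol·Å²)
    b: float = 0.92  # kcal/mol
    probe_radius: float = 1.4  # Å
    n_sphere_points: int = 960


def _select(atom_set, n: int) -> np.ndarray:
    if atom_set is None:
        return np.arange(n)
    return np.asarray(sorted(atom_set) if isinstance(atom_set, (set, frozenset)) else atom_set,
                      dtype=int)


# ---------------------------------------------------------------------------
# Finite-difference PB

def _edge_dielectric(mid: np.ndarray, centers: np.ndarray, radii: np.ndarray,
                     eps_in: float, eps_out: float) -> np.ndarray:
    """Dielectric at edge midpoints: eps_in inside any atom sphere, else eps_out."""
    inside = np.zeros(mid.shape[0], dtype=bool)
    for c, r in zip(centers, radii):
        d2 = np.einsum("ij,ij->i", mid - c, mid - c)
        inside |= d2 < r * r
    return np.where(inside, eps_in, eps_out)


def _solve_grid(origin, shape, h, centers, q, radii, eps_in, eps_out, kappa, cfg):
    """Solve the linearized PB equation on a regular grid; return phi at atoms.

    Seven-point stencil with edge-centred dielectric; charges spread to the
    eight surrounding nodes by trilinear weights; Dirichlet boundary from the
    (screened) monopole potential of the source charges.
    """
    nx, ny, nz = shape
    n = nx * ny * nz
    ax = np.arange(nx) * h + origin[0]
    ay = np.arange(ny) * h + origin[1]
    az = np.arange(nz) * h + origin[2]

    # --- edge dielectrics (harmonic mean of three samples along each edge
    # gives a smoother boundary than a single midpoint test)
    def edge_eps(axis):
        sh = list(shape)
        sh[axis] -= 1
        pts = np.stack(np.meshgrid(ax[: sh[0]] if axis == 0 else ax,
                                   ay[: sh[1]] if axis == 1 else ay,
                                   az[: sh[2]] if axis == 2 else az,
                                   indexing="ij"), axis=-1).reshape(-1, 3)
        offs = np.zeros(3)
        offs[axis] = h
        samples = []
        for frac in (0.25, 0.5, 0.75):
            samples.append(
                _edge_dielectric(pts + frac * offs, centers, radii, eps_in, eps_out)
            )
        inv = sum(1.0 / s for s in samples) / len(samples)
        return (1.0 / inv).reshape(sh)

    ex = edge_eps(0)  # (nx-1, ny, nz)
    ey = edge_eps(1)
    ez = edge_eps(2)

    def nid(i, j, k):
        return (i * ny + j) * nz + k

    # --- assemble A phi = b;  sum_edges eps (phi_nbr - phi_c) - kappa^2 h^2
    #     eps_out phi_c [exterior only] = -4 pi q_c / h
    diag = np.zeros((nx, ny, nz))
    diag[:-1, :, :] += ex
    diag[1:, :, :] += ex
    diag[:, :-1, :] += ey
    diag[:, 1:, :] += ey
    diag[:, :, :-1] += ez
    diag[:, :, 1:] += ez
    if kappa > 0.0:
        # screening applies where the medium is solvent; approximate by the
        # local mean edge dielectric being close to eps_out
        mean_eps = diag / 6.0
        screen = (mean_eps > 0.5 * (eps_in + eps_out)).astype(float)
        diag += (kappa * h) ** 2 * eps_out * screen

    rows, cols, vals = [], [], []
    idx = np.arange(n).reshape(nx, ny, nz)
    rows.append(idx.ravel()); cols.append(idx.ravel()); vals.append(diag.ravel())

    def couple(e, sl_a, sl_b):
        a = idx[sl_a].ravel()
        b = idx[sl_b].ravel()
        v = -e.ravel()
        rows.extend([a, b]); cols.extend([b, a]); vals.extend([v, v])

    couple(ex, np.s_[:-1, :, :], np.s_[1:, :, :])
    couple(ey, np.s_[:, :-1, :], np.s_[:, 1:, :])
    couple(ez, np.s_[:, :, :-1], np.s_[:, :, 1:])
    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )

    # --- trilinear charge spread
    rho = np.zeros((nx, ny, nz))
    fx = (centers[:, 0] - origin[0]) / h
    fy = (centers[:, 1] - origin[1]) / h
    fz = (centers[:, 2] - origin[2]) / h
    i0 = np.floor(fx).astype(int)
    j0 = np.floor(fy).astype(int)
    k0 = np.floor(fz).astype(int)
    tx, ty, tz = fx - i0, fy - j0, fz - k0
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                w = (np.where(di, tx, 1 - tx)
                     * np.where(dj, ty, 1 - ty)
                     * np.where(dk, tz, 1 - tz)) * q
                np.add.at(rho, (i0 + di, j0 + dj, k0 + dk), w)
    b = 4.0 * np.pi * rho.ravel() / h

    # --- Dirichlet boundary: move boundary potential to the RHS
    if cfg.boundary_condition != "zero":
        phi_b = np.zeros((nx, ny, nz))
        faces = np.zeros((nx, ny, nz), dtype=bool)
        faces[0, :, :] = faces[-1, :, :] = True
        faces[:, 0, :] = faces[:, -1, :] = True
        faces[:, :, 0] = faces[:, :, -1] = True
        pts = np.stack(np.meshgrid(ax, ay, az, indexing="ij"), axis=-1)[faces]
        d = cdist(pts, centers)
        d = np.maximum(d, 1e-6)
        phi_face = (np.exp(-kappa * d) / (eps_out * d)) @ q
        phi_b[faces] = phi_face
        # phi is fixed on the faces; solve the interior block with the
        # boundary couplings moved to the right-hand side
        interior = ~faces.ravel()
        phi = phi_b.ravel().copy()
        Aii = A[interior][:, interior]
        bi = (4.0 * np.pi * rho.ravel() / h)[interior] - A[interior][:, ~interior] @ phi[~interior]
        x0 = np.zeros(Aii.shape[0])
        sol, info = spla.cg(Aii, bi, x0=x0, rtol=cfg.rtol, maxiter=cfg.max_iter)
        if info != 0:
            res = float(np.linalg.norm(Aii @ sol - bi) / max(np.linalg.norm(bi), 1e-300))
            raise SolverError(f"PB solve did not converge (info={info}, rel residual={res:.2e})")
        phi[interior] = sol
    else:
        sol, info = spla.cg(A, b, rtol=cfg.rtol, maxiter=cfg.max_iter)
        if info != 0:
            res = float(np.linalg.norm(A @ sol - b) / max(np.linalg.norm(b), 1e-300))
            raise SolverError(f"PB solve did not converge (info={info}, rel residual={res:.2e})")
        phi = sol

    # --- trilinear interpolation of phi back to atom centres
    phi3 = phi.reshape(nx, ny, nz)
    phi_at = np.zeros(len(q))
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                w = (np.where(di, tx, 1 - tx)
                     * np.where(dj, ty, 1 - ty)
                     * np.where(dk, tz, 1 - tz))
                phi_at += w * phi3[i0 + di, j0 + dj, k0 + dk]
    return phi_at


def pb_polar_energy(
    s: StructureModel,
    t: TopologyParams,
    atom_set=None,
    cfg: PBSettings | None = None,
) -> float:
    """Polar solvation free energy (kcal/mol) of an atom set by FD-PB.

    Two solves on the identical grid — solvated (eps_in/eps_out) and vacuum
    (uniform eps_in) — are differenced at the charge sites, cancelling the
    grid self-energy of the spread charges.
    """
    cfg = cfg or PBSettings()
    sel = _select(atom_set, s.n_atoms)
    centers = s.coords[sel]
    q = t.charge[sel]
    radii = t.pb_radius[sel].copy()
    if np.any(radii <= 0):
        raise ValueError("all selected atoms need pb_radius > 0")
    if cfg.surface_def.upper() == "SES":
        radii = radii + cfg.probe_radius
    if not np.any(q):
        return 0.0

    h = cfg.grid_spacing
    lo = centers.min(axis=0) - cfg.grid_padding
    hi = centers.max(axis=0) + cfg.grid_padding
    shape = tuple(int(np.ceil((hi[d] - lo[d]) / h)) + 1 for d in range(3))
    npts = shape[0] * shape[1] * shape[2]
    if npts > cfg.max_grid_points:
        raise ResolutionError(
            f"grid of {npts} points exceeds budget {cfg.max_grid_points}; "
            "increase grid_spacing or reduce grid_padding"
        )

    phi_solv = _solve_grid(lo, shape, h, centers, q, radii,
                           cfg.eps_in, cfg.eps_out, cfg.kappa(), cfg)
    phi_vac = _solve_grid(lo, shape, h, centers, q, radii,
                          cfg.eps_in, cfg.eps_in, 0.0, cfg)
    return float(0.5 * COULOMB_CONSTANT * np.dot(q, phi_solv - phi_vac))


# ---------------------------------------------------------------------------
# Generalized Born

#: Pairwise-descreening scale factor applied to neighbour radii.  The
#: pairwise sum double-counts the volume of mutually overlapping
#: neighbours; shrinking each neighbour sphere compensates.  0.72 is the
#: conventional value for carbon-like atoms.
DESCREEN_SCALE = 0.72


def _effective_radii(centers: np.ndarray, radii: np.ndarray,
                     descreen_scale: float = DESCREEN_SCALE) -> np.ndarray:
    """Effective Born radii from the Coulomb-field approximation.

    The descreening integral of each neighbour sphere outside the atom's own
    intrinsic sphere is taken analytically, pairwise, with the neighbour
    radius scaled to compensate neighbour–neighbour overlap.  An isolated
    atom recovers its intrinsic radius exactly.
    """
    n = len(radii)
    inv = 1.0 / radii.copy()
    if n > 1:
        d = cdist(centers, centers)
        for i in range(n):
            acc = 0.0
            for j in range(n):
                if j == i:
                    continue
                rij = d[i, j]
                rj = radii[j] * descreen_scale
                if radii[i] >= rij + rj:
                    continue  # neighbour fully inside atom i's sphere
                lower = max(radii[i], rij - rj)
                upper = rij + rj
                acc += 0.5 * (
                    1.0 / lower
                    - 1.0 / upper
                    + 0.25 * (rij - rj * rj / rij) * (1.0 / upper**2 - 1.0 / lower**2)
                    + 0.5 / rij * np.log(lower / upper)
                )
            inv[i] -= acc
    if np.any(inv <= 0):
        bad = np.flatnonzero(inv <= 0)
        raise ValueError(f"non-positive effective Born radius for atoms {bad.tolist()}")
    return 1.0 / inv


def _gb_pair_matrix(centers: np.ndarray, q: np.ndarray, reff: np.ndarray,
                    eps_out: float) -> np.ndarray:
    d2 = cdist(centers, centers) ** 2
    rr = np.outer(reff, reff)
    f_gb = np.sqrt(d2 + rr * np.exp(-d2 / (4.0 * rr)))
    pref = -0.5 * COULOMB_CONSTANT * (1.0 - 1.0 / eps_out)
    return pref * np.outer(q, q) / f_gb


def gb_polar_energy(
    s: StructureModel,
    t: TopologyParams,
    atom_set=None,
    eps_out: float = 80.0,
) -> float:
    """Polar solvation free energy (kcal/mol) by pairwise generalized Born.

    Still functional form with CFA effective radii; reduces to the Born
    expression for a single atom.
    """
    sel = _select(atom_set, s.n_atoms)
    q = t.charge[sel]
    if not np.any(q):
        return 0.0
    reff = _effective_radii(s.coords[sel], t.pb_radius[sel])
    return float(np.sum(_gb_pair_matrix(s.coords[sel], q, reff, eps_out)))


def gb_polar_energy_per_atom(
    s: StructureModel,
    t: TopologyParams,
    atom_set=None,
    eps_out: float = 80.0,
) -> np.ndarray:
    """Per-atom partition of the GB polar energy (half of each pair term
    to each partner); sums to :func:`gb_polar_energy` exactly."""
    sel = _select(atom_set, s.n_atoms)
    q = t.charge[sel]
    if not np.any(q):
        return np.zeros(sel.size)
    reff = _effective_radii(s.coords[sel], t.pb_radius[sel])
    m = _gb_pair_matrix(s.coords[sel], q, reff, eps_out)
    return 0.5 * (m.sum(axis=0) + m.sum(axis=1))


# ---------------------------------------------------------------------------
# SASA

def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(
    s: StructureModel,
    t: TopologyParams,
    atom_set=None,
    cfg: NonpolarModel | None = None,
) -> tuple[float, np.ndarray]:
    """Solvent-accessible surface area (Å²) of an atom set.

    Sphere-point method: each atom's sphere is inflated by the probe radius
    and sampled with a deterministic Fibonacci point set; points falling
    inside any *other* inflated sphere of the same set are buried.  Only
    atoms in ``atom_set`` occlude — the set is treated as an isolated solute.

    Returns ``(total, per_atom)``.
    """
    cfg = cfg or NonpolarModel()
    sel = _select(atom_set, s.n_atoms)
    centers = s.coords[sel]
    radii = t.pb_radius[sel] + cfg.probe_radius
    unit = _fibonacci_sphere(cfg.n_sphere_points)
    n = sel.size
    per_atom = np.zeros(n)
    d = cdist(centers, centers) if n > 1 else np.zeros((1, 1))
    for i in range(n):
        pts = centers[i] + radii[i] * unit
        exposed = np.ones(cfg.n_sphere_points, dtype=bool)
        neighbours = np.flatnonzero((d[i] < radii[i] + radii) & (np.arange(n) != i))
        for j in neighbours:
            d2 = np.einsum("ij,ij->i", pts - centers[j], pts - centers[j])
            exposed &= d2 >= radii[j] ** 2
            if not exposed.any():
                break
        per_atom[i] = 4.0 * np.pi * radii[i] ** 2 * exposed.mean()
    return float(per_atom.sum()), per_atom


def nonpolar_energy(area: float, cfg: NonpolarModel | None = None) -> float:
    """Nonpolar solvation free energy ``gamma * area + b`` (kcal/mol)."""
    cfg = cfg or NonpolarModel()
    return cfg.gamma * area + cfg.b
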