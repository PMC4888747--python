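"""Trajectory stability metrics: RMSD, B-factors, contact maps, H-bonds.

Superposition uses the Kabsch (SVD) least-squares rigid fit.  B-factors are
``(8 pi^2 / 3) <|r - <r>|^2>`` after per-frame superposition.  Contact maps
are residue-by-residue mean distances between designated reference atoms
(C-alpha for proteins).  Hydrogen bonds are tracked by heavy-atom
donor–acceptor distance with an occupancy cutoff; no angular criterion is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structio import FrameEnsemble, StructureModel

__all__ = [
    "RmsdSeries",
    "ContactMap",
    "HBondSeries",
    "kabsch",
    "superpose_rmsd",
    "cross_structure_rmsd",
    "bfactors",
    "contact_map",
    "diff_map",
    "hbond_series",
]

BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass
class RmsdSeries:
    """Per-frame RMSD (Å) of a named selection against a reference."""

    values: np.ndarray
    selection: np.ndarray
    fit_selection: np.ndarray


@dataclass
class ContactMap:
    """Residue × residue mean reference-atom distance matrix (Å)."""

    distances: np.ndarray  # (R, R)
    residues: np.ndarray  # residue indices, length R


@dataclass
class HBondSeries:
    """Distance series and occupancy for declared donor–acceptor pairs."""

    pairs: list[tuple[int, int]]
    distances: np.ndarray  # (n_frames, n_pairs) Å
    occupancy: np.ndarray  # (n_pairs,) fraction of frames below cutoff
    cutoff: float


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t minimizing |R·mobile + t - target|².

    Proper rotation only (reflections are corrected).
    """
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, tc - rot @ mc


def _apply(rot: np.ndarray, trans: np.ndarray, x: np.ndarray) -> np.ndarray:
    return x @ rot.T + trans


def _sel(selection, n: int) -> np.ndarray:
    if selection is None:
        return np.arange(n)
    return np.asarray(sorted(selection) if isinstance(selection, (set, frozenset)) else selection,
                      dtype=int)


def superpose_rmsd(
    ref: StructureModel,
    frames: FrameEnsemble,
    selection=None,
    fit_selection=None,
) -> RmsdSeries:
    """Per-frame RMSD of ``selection`` after a Kabsch fit on ``fit_selection``.

    By default the fit and measurement selections coincide.  Fitting on one
    selection (e.g. the backbone) and measuring another (e.g. the ligand)
    reports how much the second moves in the frame of the first.
    """
    sel = _sel(selection, ref.n_atoms)
    fit = sel if fit_selection is None else _sel(fit_selection, ref.n_atoms)
    ref_fit = ref.coords[fit]
    ref_sel = ref.coords[sel]
    out = np.empty(frames.n_frames)
    for k, frame in enumerate(frames.frames):
        rot, trans = kabsch(frame[fit], ref_fit)
        moved = _apply(rot, trans, frame[sel])
        out[k] = np.sqrt(np.mean(np.sum((moved - ref_sel) ** 2, axis=1)))
    return RmsdSeries(out, sel, fit)


def cross_structure_rmsd(a: StructureModel, b: StructureModel) -> float:
    """Backbone RMSD between two structures after sequence-position matching.

    Only backbone atoms (N/CA/C/O) of residues present in both structures
    are compared, so mutated side chains are excluded by construction.
    """
    def backbone(s: StructureModel) -> dict[tuple[int, str], int]:
        return {
            (int(s.residue_index[i]), s.atom_names[i]): i
            for i in range(s.n_atoms)
            if s.atom_names[i] in BACKBONE_NAMES
        }

    ba, bb = backbone(a), backbone(b)
    common = sorted(set(ba) & set(bb))
    if len(common) < 3:
        raise ValueError("fewer than 3 common backbone atoms")
    xa = a.coords[[ba[k] for k in common]]
    xb = b.coords[[bb[k] for k in common]]
    rot, trans = kabsch(xb, xa)
    moved = _apply(rot, trans, xb)
    return float(np.sqrt(np.mean(np.sum((moved - xa) ** 2, axis=1))))


def bfactors(
    frames: FrameEnsemble,
    selection=None,
    superpose: bool = True,
) -> np.ndarray:
    """Per-atom B-factors (Å²) of the selection.

    ``B_i = (8 pi^2 / 3) <|r_i - <r_i>|^2>`` with frames first superposed
    (Kabsch on the selection, against the first frame) unless ``superpose``
    is disabled for ensembles already expressed in a common frame.
    """
    sel = _sel(selection, frames.n_atoms)
    if frames.n_frames < 2:
        raise ValueError("B-factors need at least two frames (variance undefined)")
    x = frames.frames[:, sel, :]
    if superpose:
        ref = x[0]
        aligned = np.empty_like(x)
        for k in range(x.shape[0]):
            rot, trans = kabsch(x[k], ref)
            aligned[k] = _apply(rot, trans, x[k])
        x = aligned
    mean = x.mean(axis=0)
    msf = np.mean(np.sum((x - mean) ** 2, axis=2), axis=0)
    return (8.0 * np.pi**2 / 3.0) * msf


def residue_bfactors(
    s: StructureModel,
    frames: FrameEnsemble,
    selection=None,
    superpose: bool = True,
) -> dict[int, float]:
    """Mean B-factor over each residue's selected atoms."""
    sel = _sel(selection, frames.n_atoms)
    b = bfactors(frames, sel, superpose=superpose)
    out: dict[int, float] = {}
    res = s.residue_index[sel]
    for r in np.unique(res):
        out[int(r)] = float(b[res == r].mean())
    return out


def contact_map(
    s: StructureModel,
    frames: FrameEnsemble,
    atom_name: str = "CA",
) -> ContactMap:
    """Mean pairwise distance between each residue's reference atom.

    One reference atom (default name ``CA``) is taken per residue; residues
    lacking it are skipped.  The matrix is symmetric with a zero diagonal.
    """
    picks: dict[int, int] = {}
    for i in range(s.n_atoms):
        r = int(s.residue_index[i])
        if s.atom_names[i] == atom_name and r not in picks:
            picks[r] = i
    residues = np.array(sorted(picks))
    idx = np.array([picks[r] for r in residues])
    acc = np.zeros((idx.size, idx.size))
    for frame in frames.frames:
        x = frame[idx]
        d = np.sqrt(np.maximum(0.0, np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=2)))
        acc += d
    return ContactMap(acc / frames.n_frames, residues)


def diff_map(a: ContactMap, b: ContactMap) -> ContactMap:
    """Difference map ``a - b`` between two systems (same residue grid)."""
    if not np.array_equal(a.residues, b.residues):
        raise ValueError("contact maps cover different residue sets")
    return ContactMap(a.distances - b.distances, a.residues)


def hbond_series(
    frames: FrameEnsemble,
    pairs: list[tuple[int, int]],
    cutoff: float = 3.5,
) -> HBondSeries:
    """Heavy-atom donor–acceptor distance series and occupancy per pair."""
    pairs = [(int(i), int(j)) for i, j in pairs]
    d = np.empty((frames.n_frames, len(pairs)))
    for c, (i, j) in enumerate(pairs):
        diff = frames.frames[:, i, :] - frames.frames[:, j, :]
        d[:, c] = np.sqrt(np.einsum("ij,ij->i", diff, diff))
    return HBondSeries(pairs, d, (d < cutoff).mean(axis=0), cutoff)
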