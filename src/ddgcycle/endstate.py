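"""Single-trajectory end-state (MM/PBSA-style) free-energy assembly.

For each snapshot of the complex trajectory the receptor and ligand
conformations are taken as subsets of the complex frame (the
single-trajectory protocol), so bonded and intramolecular nonbonded terms
cancel exactly in the enthalpy difference, which reduces to

    dE_ele + dE_vdw   (gas-phase interaction)
  + dE_np             (nonpolar solvation change, gamma*dA - b)
  + dE_pb             (polar solvation change)

Ensemble means over a frame window, a lag-1-autocorrelation-corrected
standard error, and the final assembly

    dE_es = dE_ele + dE_pb
    dH    = dE_ele + dE_vdw + dE_np + dE_pb
    dG    = dH + (-T dS)

are collected in :class:`FreeEnergySummary`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forcefield import _coulomb, _lj, bonded_energy
from .solvation import NonpolarModel, PBSettings, gb_polar_energy, pb_polar_energy, sasa
from .structio import FrameEnsemble, StructureModel, TopologyParams, check_congruence

__all__ = [
    "SnapshotEnergies",
    "FreeEnergySummary",
    "single_trajectory_frames",
    "component_energies",
    "summarize",
]


@dataclass
class SnapshotEnergies:
    """Per-frame binding energy components (kcal/mol)."""

    e_ele: np.ndarray
    e_vdw: np.ndarray
    e_np: np.ndarray
    e_pb: np.ndarray

    def __post_init__(self) -> None:
        for name in ("e_ele", "e_vdw", "e_np", "e_pb"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != self.e_ele.shape:
                raise ValueError("component arrays must have equal length")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {name}")

    @property
    def n_frames(self) -> int:
        return self.e_ele.shape[0]

    @property
    def dh(self) -> np.ndarray:
        """Per-frame enthalpy series."""
        return self.e_ele + self.e_vdw + self.e_np + self.e_pb


@dataclass
class FreeEnergySummary:
    """Ensemble-averaged binding free-energy components (kcal/mol)."""

    e_ele: float
    e_vdw: float
    e_np: float
    e_pb: float
    e_es: float
    dh: float
    minus_t_ds: float
    dg: float
    sem_dg: float = 0.0
    n_frames_enthalpy: int = 0
    n_frames_entropy: int = 0

    def __post_init__(self) -> None:
        if abs(self.e_es - (self.e_ele + self.e_pb)) > 1e-8:
            raise ValueError("e_es must equal e_ele + e_pb")
        if abs(self.dh - (self.e_ele + self.e_vdw + self.e_np + self.e_pb)) > 1e-8:
            raise ValueError("dh must equal the sum of the four components")
        if abs(self.dg - (self.dh + self.minus_t_ds)) > 1e-8:
            raise ValueError("dg must equal dh + minus_t_ds")

    @classmethod
    def from_components(
        cls,
        e_ele: float,
        e_vdw: float,
        e_np: float,
        e_pb: float,
        minus_t_ds: float = 0.0,
        sem_dg: float = 0.0,
        n_frames_enthalpy: int = 0,
        n_frames_entropy: int = 0,
    ) -> "FreeEnergySummary":
        """Assemble a summary from component means (e.g. a published table)."""
        dh = e_ele + e_vdw + e_np + e_pb
        return cls(
            e_ele=e_ele,
            e_vdw=e_vdw,
            e_np=e_np,
            e_pb=e_pb,
            e_es=e_ele + e_pb,
            dh=dh,
            minus_t_ds=minus_t_ds,
            dg=dh + minus_t_ds,
            sem_dg=sem_dg,
            n_frames_enthalpy=n_frames_enthalpy,
            n_frames_entropy=n_frames_entropy,
        )


def single_trajectory_frames(
    complex_frames: FrameEnsemble,
    t: TopologyParams,
) -> tuple[FrameEnsemble, FrameEnsemble]:
    """Receptor and ligand ensembles extracted from the complex trajectory.

    Coordinates are bit-identical subsets of each complex frame, which is
    what makes bonded and intramolecular terms cancel exactly downstream.
    """
    if np.intersect1d(t.receptor_atoms, t.ligand_atoms).size:
        raise ValueError("receptor and ligand atom sets overlap")
    if t.receptor_atoms.size == 0 or t.ligand_atoms.size == 0:
        raise ValueError("both receptor and ligand atom sets must be non-empty")
    return complex_frames.subset(t.receptor_atoms), complex_frames.subset(t.ligand_atoms)


def component_energies(
    frames: FrameEnsemble,
    s: StructureModel,
    t: TopologyParams,
    nonpolar: NonpolarModel | None = None,
    solvation: str = "gb",
    pb_settings: PBSettings | None = None,
    eps_out: float = 80.0,
    stride: int = 1,
) -> SnapshotEnergies:
    """Per-snapshot binding components ``dX = X_complex - X_receptor - X_ligand``.

    Gas-phase terms are evaluated as the receptor–ligand interaction (their
    exact single-trajectory difference).  ``dE_np`` comes from the SASA
    difference through the linear nonpolar model (the constant ``b`` enters
    once per species, hence a net ``-b``).  Polar solvation uses the GB fast
    path by default; ``solvation="pb"`` runs three grid solves per frame,
    ``solvation="none"`` skips the polar term.

    If the ensemble carries an injected extra interaction channel it is
    added to ``dE_ele``.
    """
    check_congruence(s, t, frames)
    nonpolar = nonpolar or NonpolarModel()
    ir, il = t.receptor_atoms, t.ligand_atoms
    if ir.size == 0 or il.size == 0:
        raise ValueError("receptor and ligand atom sets must be non-empty")
    both = np.concatenate([ir, il])
    idx = range(0, frames.n_frames, stride)
    ele, vdw, e_np, e_pb = [], [], [], []
    for f in idx:
        sf = s.with_coords(frames.frames[f])
        ele.append(_coulomb(sf.coords, t.charge, ir, il))
        vdw.append(_lj(sf.coords, t.lj_rmin_half, t.lj_epsilon, ir, il))
        a_c, _ = sasa(sf, t, both, nonpolar)
        a_r, _ = sasa(sf, t, ir, nonpolar)
        a_l, _ = sasa(sf, t, il, nonpolar)
        e_np.append(nonpolar.gamma * (a_c - a_r - a_l) - nonpolar.b)
        if solvation == "gb":
            e_pb.append(
                gb_polar_energy(sf, t, both, eps_out)
                - gb_polar_energy(sf, t, ir, eps_out)
                - gb_polar_energy(sf, t, il, eps_out)
            )
        elif solvation == "pb":
            cfg = pb_settings or PBSettings()
            e_pb.append(
                pb_polar_energy(sf, t, both, cfg)
                - pb_polar_energy(sf, t, ir, cfg)
                - pb_polar_energy(sf, t, il, cfg)
            )
        elif solvation == "none":
            e_pb.append(0.0)
        else:
            raise ValueError(f"unknown solvation method {solvation!r}")
    ele = np.array(ele)
    if frames.extra_interaction is not None:
        ele = ele + frames.extra_interaction[list(idx)]
    return SnapshotEnergies(ele, np.array(vdw), np.array(e_np), np.array(e_pb))


def delta_bonded(frame: np.ndarray, s: StructureModel, t: TopologyParams) -> float:
    """Explicit ``dE_bonded`` of one frame under the single-trajectory
    protocol — identically zero; provided so the cancellation is checkable."""
    sf = s.with_coords(frame)
    both = np.concatenate([t.receptor_atoms, t.ligand_atoms])
    return (
        bonded_energy(sf, t, both)
        - bonded_energy(sf, t, t.receptor_atoms)
        - bonded_energy(sf, t, t.ligand_atoms)
    )


def _n_effective(x: np.ndarray) -> float:
    """Effective sample size from the lag-1 autocorrelation of the series."""
    n = x.size
    if n < 3:
        return float(n)
    d = x - x.mean()
    var = float(np.dot(d, d))
    if var == 0.0:
        return float(n)
    rho1 = float(np.dot(d[:-1], d[1:]) / var)
    rho1 = min(max(rho1, -0.999), 0.999)
    return float(np.clip(n * (1.0 - rho1) / (1.0 + rho1), 1.0, n))


def summarize(
    se: SnapshotEnergies,
    minus_t_ds: float = 0.0,
    frame_window: tuple[int, int] | None = None,
    entropy_sem: float = 0.0,
    n_frames_entropy: int = 0,
) -> FreeEnergySummary:
    """Average the per-frame components over a window and assemble dG.

    ``frame_window`` is an inclusive (start, end) frame-index range.  The
    standard error of dG combines the enthalpy-series standard error,
    corrected for lag-1 autocorrelation, with ``entropy_sem`` in quadrature.
    """
    sl = slice(None)
    if frame_window is not None:
        start, end = frame_window
        sl = slice(start, end + 1)
    comp = {name: np.asarray(getattr(se, name))[sl] for name in ("e_ele", "e_vdw", "e_np", "e_pb")}
    n = comp["e_ele"].shape[0]
    if n == 0:
        raise ValueError("frame window selects no frames")
    dh_series = comp["e_ele"] + comp["e_vdw"] + comp["e_np"] + comp["e_pb"]
    if n > 1:
        sem_h = float(np.std(dh_series, ddof=1) / np.sqrt(_n_effective(dh_series)))
    else:
        sem_h = 0.0
    return FreeEnergySummary.from_components(
        float(comp["e_ele"].mean()),
        float(comp["e_vdw"].mean()),
        float(comp["e_np"].mean()),
        float(comp["e_pb"].mean()),
        minus_t_ds=minus_t_ds,
        sem_dg=float(np.hypot(sem_h, entropy_sem)),
        n_frames_enthalpy=n,
        n_frames_entropy=n_frames_entropy,
    )
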