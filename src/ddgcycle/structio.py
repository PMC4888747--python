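"""Structure, topology and coordinate-ensemble I/O.

Defines the three containers every other stage consumes:

* :class:`StructureModel` — atoms with names, residue assignments and
  coordinates (Å).  Atom order is canonical: every index used elsewhere in
  the package refers to the position of an atom in this list.
* :class:`TopologyParams` — per-atom charges (e), 12-6 Lennard-Jones
  parameters, masses, intrinsic (PB) radii, a harmonic bond list, and the
  receptor / ligand atom-index sets.
* :class:`FrameEnsemble` — an ordered stack of coordinate frames standing in
  for molecular-dynamics snapshots.

File formats
------------
Structures use fixed-column PDB.  Topologies and frames use line-oriented
whitespace-delimited text with ``#`` comments:

Topology::

    natoms N
    <index> <charge> <lj_rmin_half> <lj_epsilon> <mass> <pb_radius>   (N rows)
    bonds B
    <i> <j> <force_constant> <equilibrium_length>                     (B rows)
    receptor <i> <i> ...
    ligand <i> <i> ...

Frames::

    natoms N nframes M
    <x> <y> <z>        (M blocks of N rows)

Indices are 0-based inside the package; PDB serial/residue numbers are
1-based only at the file boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "StructureModel",
    "TopologyParams",
    "FrameEnsemble",
    "FormatError",
    "EmptyStructureError",
    "CongruenceError",
    "read_pdb",
    "write_pdb",
    "read_topology",
    "write_topology",
    "read_frames",
    "write_frames",
    "check_congruence",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class EmptyStructureError(FormatError):
    """A structure file contained no atoms."""


class CongruenceError(ValueError):
    """Structure, topology and frames do not describe the same atom list."""


@dataclass
class StructureModel:
    """Atoms with coordinates; the geometric object all stages consume.

    Parallel arrays indexed by canonical atom index.  ``residue_index`` is a
    dense 0-based index assigned in order of first appearance.
    """

    atom_names: list[str]
    elements: list[str]
    residue_index: np.ndarray  # (N,) int
    residue_names: list[str]
    chain_ids: list[str]
    coords: np.ndarray  # (N, 3) float, Å

    def __post_init__(self) -> None:
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.atom_names)
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords shape {self.coords.shape} != ({n}, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        # residue indices must be non-decreasing within each chain
        for chain in set(self.chain_ids):
            idx = [self.residue_index[i] for i in range(n) if self.chain_ids[i] == chain]
            if any(b < a for a, b in zip(idx, idx[1:])):
                raise ValueError(f"residue_index not non-decreasing in chain {chain!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        """A copy of this structure carrying different coordinates."""
        return StructureModel(
            self.atom_names,
            self.elements,
            self.residue_index,
            self.residue_names,
            self.chain_ids,
            np.asarray(coords, dtype=float),
        )

    def residue_atoms(self, residue: int) -> np.ndarray:
        """Canonical indices of the atoms belonging to ``residue``."""
        return np.flatnonzero(self.residue_index == residue)

    def residue_label(self, residue: int) -> str:
        atoms = self.residue_atoms(residue)
        if atoms.size == 0:
            raise KeyError(f"no residue with index {residue}")
        return f"{self.residue_names[atoms[0]]}{residue + 1}"


@dataclass
class TopologyParams:
    """Force-field parameters paired with a :class:`StructureModel`."""

    charge: np.ndarray  # (N,) e
    lj_rmin_half: np.ndarray  # (N,) Å
    lj_epsilon: np.ndarray  # (N,) kcal/mol
    mass: np.ndarray  # (N,) amu
    pb_radius: np.ndarray  # (N,) Å
    bonds: list[tuple[int, int, float, float]] = field(default_factory=list)
    receptor_atoms: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    ligand_atoms: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        for name in ("charge", "lj_rmin_half", "lj_epsilon", "mass", "pb_radius"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.receptor_atoms = np.asarray(self.receptor_atoms, dtype=int)
        self.ligand_atoms = np.asarray(self.ligand_atoms, dtype=int)
        n = self.charge.shape[0]
        for name in ("lj_rmin_half", "lj_epsilon", "mass", "pb_radius"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} length != natoms")
        if np.any(self.lj_epsilon < 0):
            raise ValueError("lj_epsilon must be >= 0")
        if np.any(self.lj_rmin_half <= 0) or np.any(self.mass <= 0) or np.any(self.pb_radius <= 0):
            raise ValueError("lj_rmin_half, mass, pb_radius must be > 0")
        if np.intersect1d(self.receptor_atoms, self.ligand_atoms).size:
            raise ValueError("receptor and ligand atom sets overlap")

    @property
    def n_atoms(self) -> int:
        return self.charge.shape[0]

    def copy(self) -> "TopologyParams":
        return TopologyParams(
            self.charge.copy(),
            self.lj_rmin_half.copy(),
            self.lj_epsilon.copy(),
            self.mass.copy(),
            self.pb_radius.copy(),
            [tuple(b) for b in self.bonds],
            self.receptor_atoms.copy(),
            self.ligand_atoms.copy(),
        )


@dataclass
class FrameEnsemble:
    """Ordered coordinate frames congruent with a :class:`StructureModel`.

    ``extra_interaction`` is an optional per-frame energy channel (kcal/mol)
    carried alongside the coordinates; the synthetic generator uses it to
    inject a known receptor–ligand coupling that downstream analysis must
    recover.  It is added to the electrostatic interaction channel.
    """

    frames: np.ndarray  # (M, N, 3) Å
    frame_times: np.ndarray | None = None  # (M,) ps
    extra_interaction: np.ndarray | None = None  # (M,) kcal/mol

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (M, N, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("ensemble needs at least one frame")
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if self.frame_times.shape != (self.n_frames,):
                raise ValueError("frame_times length mismatch")
        if self.extra_interaction is not None:
            self.extra_interaction = np.asarray(self.extra_interaction, dtype=float)
            if self.extra_interaction.shape != (self.n_frames,):
                raise ValueError("extra_interaction length mismatch")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def subset(self, atom_indices: np.ndarray) -> "FrameEnsemble":
        """Frames restricted to a set of atoms (coordinates shared, bit-identical)."""
        return FrameEnsemble(self.frames[:, np.asarray(atom_indices, dtype=int), :],
                             frame_times=self.frame_times)


# ---------------------------------------------------------------------------
# PDB

_PDB_RECORDS = ("ATOM  ", "HETATM", "ATOM", "HETATM")


def read_pdb(path: str | Path) -> StructureModel:
    """Read a fixed-column PDB file into a :class:`StructureModel`.

    ATOM and HETATM records are treated identically, in file order.
    Alternate locations other than blank or 'A' are dropped.  Residues are
    renumbered to a dense 0-based index in order of first appearance of each
    (chain, residue number, insertion code) key.
    """
    path = Path(path)
    names: list[str] = []
    elements: list[str] = []
    res_keys: list[tuple] = []
    res_names: list[str] = []
    chains: list[str] = []
    xyz: list[tuple[float, float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec.rstrip() not in ("ATOM", "HETATM"):
                continue
            altloc = line[16:17]
            if altloc not in (" ", "", "A"):
                continue
            try:
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as exc:
                raise FormatError(
                    f"{path.name}, line {lineno}: unparseable coordinate field ({exc})"
                ) from None
            name = line[12:16].strip()
            resname = line[17:20].strip()
            chain = line[21:22].strip() or "A"
            resseq = line[22:26].strip()
            icode = line[26:27].strip()
            element = line[76:78].strip() if len(line) >= 78 else ""
            if not element:
                element = name[:1] if name else "X"
            names.append(name)
            elements.append(element)
            res_keys.append((chain, resseq, icode))
            res_names.append(resname)
            chains.append(chain)
            xyz.append((x, y, z))
    if not names:
        raise EmptyStructureError(f"{path.name}: no ATOM/HETATM records")
    index_of: dict[tuple, int] = {}
    residx = np.empty(len(names), dtype=int)
    for i, key in enumerate(res_keys):
        if key not in index_of:
            index_of[key] = len(index_of)
        residx[i] = index_of[key]
    return StructureModel(names, elements, residx, res_names, chains, np.array(xyz))


def write_pdb(s: StructureModel, path: str | Path) -> None:
    """Write a fixed-column PDB file (coordinates to 3 decimals)."""
    with open(path, "w") as fh:
        for i in range(s.n_atoms):
            name = s.atom_names[i]
            resname = s.residue_names[i]
            if len(resname) > 3:
                logger.warning("residue name %r truncated to 3 characters", resname)
                resname = resname[:3]
            # atom names of up to 3 chars start in column 14 by convention
            field_name = name if len(name) >= 4 else f" {name}"
            x, y, z = s.coords[i]
            fh.write(
                f"ATOM  {i + 1:5d} {field_name:<4s} {resname:<3s} {s.chain_ids[i][:1]:1s}"
                f"{int(s.residue_index[i]) + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {s.elements[i][:2]:>2s}\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Topology

def _tokens(path: Path):
    """Yield (lineno, token-list) for non-empty, non-comment lines."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if line:
                yield lineno, line.split()


def read_topology(path: str | Path) -> TopologyParams:
    path = Path(path)
    lines = list(_tokens(path))
    if not lines:
        raise FormatError(f"{path.name}: empty topology file")
    pos = 0

    def expect(keyword: str) -> list[str]:
        nonlocal pos
        if pos >= len(lines):
            raise FormatError(f"{path.name}: expected '{keyword}', got end of file")
        lineno, toks = lines[pos]
        if toks[0] != keyword:
            raise FormatError(f"{path.name}, line {lineno}: expected '{keyword}', got {toks[0]!r}")
        pos += 1
        return toks

    toks = expect("natoms")
    natoms = int(toks[1])
    cols = np.empty((natoms, 6))
    for k in range(natoms):
        if pos >= len(lines):
            raise FormatError(f"{path.name}: declared natoms {natoms} but found {k} atom rows")
        lineno, toks = lines[pos]
        pos += 1
        if len(toks) != 6:
            raise FormatError(f"{path.name}, line {lineno}: expected 6 fields per atom row")
        try:
            cols[k] = [float(t) for t in toks]
        except ValueError as exc:
            raise FormatError(f"{path.name}, line {lineno}: {exc}") from None
    toks = expect("bonds")
    nbonds = int(toks[1])
    bonds = []
    for k in range(nbonds):
        if pos >= len(lines):
            raise FormatError(f"{path.name}: declared bonds {nbonds} but found {k} rows")
        lineno, toks = lines[pos]
        pos += 1
        bonds.append((int(toks[0]), int(toks[1]), float(toks[2]), float(toks[3])))
    receptor = np.array([], dtype=int)
    ligand = np.array([], dtype=int)
    while pos < len(lines):
        lineno, toks = lines[pos]
        pos += 1
        if toks[0] == "receptor":
            receptor = np.array([int(t) for t in toks[1:]], dtype=int)
        elif toks[0] == "ligand":
            ligand = np.array([int(t) for t in toks[1:]], dtype=int)
        else:
            raise FormatError(f"{path.name}, line {lineno}: unknown section {toks[0]!r}")
    return TopologyParams(
        charge=cols[:, 1],
        lj_rmin_half=cols[:, 2],
        lj_epsilon=cols[:, 3],
        mass=cols[:, 4],
        pb_radius=cols[:, 5],
        bonds=bonds,
        receptor_atoms=receptor,
        ligand_atoms=ligand,
    )


def write_topology(t: TopologyParams, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# index charge lj_rmin_half lj_epsilon mass pb_radius\n")
        fh.write(f"natoms {t.n_atoms}\n")
        for i in range(t.n_atoms):
            fh.write(
                f"{i} {t.charge[i]:.17g} {t.lj_rmin_half[i]:.17g} {t.lj_epsilon[i]:.17g} "
                f"{t.mass[i]:.17g} {t.pb_radius[i]:.17g}\n"
            )
        fh.write(f"bonds {len(t.bonds)}\n")
        for i, j, k, r0 in t.bonds:
            fh.write(f"{i} {j} {k:.17g} {r0:.17g}\n")
        if t.receptor_atoms.size:
            fh.write("receptor " + " ".join(str(i) for i in t.receptor_atoms) + "\n")
        if t.ligand_atoms.size:
            fh.write("ligand " + " ".join(str(i) for i in t.ligand_atoms) + "\n")


# ---------------------------------------------------------------------------
# Frames

def read_frames(path: str | Path) -> FrameEnsemble:
    path = Path(path)
    lines = list(_tokens(path))
    if not lines:
        raise FormatError(f"{path.name}: empty frames file")
    lineno, toks = lines[0]
    if len(toks) != 4 or toks[0] != "natoms" or toks[2] != "nframes":
        raise FormatError(f"{path.name}, line {lineno}: expected 'natoms N nframes M' header")
    natoms, nframes = int(toks[1]), int(toks[3])
    rows = lines[1:]
    if len(rows) != natoms * nframes:
        raise FormatError(
            f"{path.name}: header declares {nframes} frames x {natoms} atoms = "
            f"{natoms * nframes} rows, found {len(rows)}"
        )
    frames = np.empty((nframes, natoms, 3))
    for k, (lineno, toks) in enumerate(rows):
        if len(toks) != 3:
            raise FormatError(f"{path.name}, line {lineno}: expected 3 coordinates per row")
        try:
            frames[k // natoms, k % natoms] = [float(t) for t in toks]
        except ValueError as exc:
            raise FormatError(f"{path.name}, line {lineno}: {exc}") from None
    return FrameEnsemble(frames)


def write_frames(e: FrameEnsemble, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"natoms {e.n_atoms} nframes {e.n_frames}\n")
        for frame in e.frames:
            for x, y, z in frame:
                fh.write(f"{x:.17g} {y:.17g} {z:.17g}\n")


# ---------------------------------------------------------------------------

def check_congruence(
    s: StructureModel,
    t: TopologyParams | None = None,
    e: FrameEnsemble | None = None,
) -> None:
    """Verify that a (structure, topology, frames) triple shares one atom list.

    Raises :class:`CongruenceError` on any mismatch.
    """
    if t is not None:
        if t.n_atoms != s.n_atoms:
            raise CongruenceError(f"topology has {t.n_atoms} atoms, structure {s.n_atoms}")
        for name, idx in (("receptor", t.receptor_atoms), ("ligand", t.ligand_atoms)):
            if idx.size and (idx.min() < 0 or idx.max() >= s.n_atoms):
                raise CongruenceError(f"{name} atom set out of range")
        for i, j, _, _ in t.bonds:
            if not (0 <= i < s.n_atoms and 0 <= j < s.n_atoms):
                raise CongruenceError(f"bond ({i}, {j}) out of range")
    if e is not None and e.n_atoms != s.n_atoms:
        raise CongruenceError(f"frames have {e.n_atoms} atoms, structure {s.n_atoms}")
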