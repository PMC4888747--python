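"""Published MM/PBSA component values for streptavidin–biotin binding.

Reference data for the wild-type streptavidin–biotin complex and its S45A,
D128A and S45A/D128A ("DM") mutants: ensemble-averaged binding energy
components (kcal/mol) and the per-residue enthalpy decomposition over the
eight first-shell residues plus the ligand's self term.  These values are
consumed as *inputs* to the cycle arithmetic — the package does not attempt
to regenerate them, which would require the underlying explicit-solvent
trajectories.
"""

from __future__ import annotations

from .endstate import FreeEnergySummary

__all__ = [
    "COMPONENTS",
    "RESIDUE_ENTHALPY",
    "summary",
    "SYSTEMS",
]

SYSTEMS = ("WT", "S45A", "D128A", "DM")

#: Ensemble means of the binding components, kcal/mol:
#: (dE_ele, dE_vdw, dE_np, dE_pb, -T dS, sem_dG).
COMPONENTS: dict[str, tuple[float, float, float, float, float, float]] = {
    "WT": (-103.64, -30.76, -3.37, 76.33, 20.27, 0.36),
    "S45A": (-95.06, -31.02, -3.40, 73.59, 19.99, 0.36),
    "D128A": (-128.72, -29.13, -3.45, 108.35, 18.63, 0.37),
    "DM": (-124.39, -29.06, -3.51, 111.10, 19.49, 0.37),
}

#: Per-residue enthalpy contributions (kcal/mol) for the eight residues in
#: direct contact with biotin, plus the ligand's own (self + desolvation)
#: term, per system.
RESIDUE_ENTHALPY: dict[str, dict[str, float]] = {
    "WT": {
        "S(A)45": -7.46, "D(A)128": -14.00, "N23": -5.80, "S27": -18.31,
        "Y43": -18.46, "N49": -15.44, "S88": -11.73, "T90": -5.30,
        "biotin": 50.27,
    },
    "S45A": {
        "S(A)45": -4.17, "D(A)128": -13.90, "N23": -5.77, "S27": -16.22,
        "Y43": -17.34, "N49": -19.45, "S88": -11.81, "T90": -3.95,
        "biotin": 50.12,
    },
    "D128A": {
        "S(A)45": -8.23, "D(A)128": -0.20, "N23": 0.27, "S27": -16.86,
        "Y43": -17.53, "N49": -14.32, "S88": -14.58, "T90": -4.94,
        "biotin": 46.11,
    },
    "DM": {
        "S(A)45": -5.02, "D(A)128": -0.15, "N23": 0.23, "S27": -16.92,
        "Y43": -17.71, "N49": -12.63, "S88": -12.23, "T90": -5.46,
        "biotin": 43.47,
    },
}

#: Enthalpy / entropy snapshot counts behind the published averages.
N_FRAMES_ENTHALPY = 800
N_FRAMES_ENTROPY = 100


def summary(system: str) -> FreeEnergySummary:
    """Published component means of one system assembled into a
    :class:`~ddgcycle.endstate.FreeEnergySummary`."""
    ele, vdw, np_, pb, mtds, sem = COMPONENTS[system]
    return FreeEnergySummary.from_components(
        ele, vdw, np_, pb,
        minus_t_ds=mtds,
        sem_dg=sem,
        n_frames_enthalpy=N_FRAMES_ENTHALPY,
        n_frames_entropy=N_FRAMES_ENTROPY,
    )
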