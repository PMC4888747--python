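"""Double-mutant thermodynamic-cycle bookkeeping.

Given free-energy summaries for the wild type, two single mutants and the
double mutant, this module forms the per-channel perturbations relative to
wild type, the additive prediction for the double mutant
(``WT + ddA + ddB``), and the cooperativity

    coop = calculated - predicted = X_double - X_mutA - X_mutB + X_WT

for every thermodynamic channel, plus the analogous per-residue
decomposition of the enthalpy contributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .endstate import FreeEnergySummary

__all__ = [
    "CHANNELS",
    "CycleResult",
    "delta_vs_wt",
    "cycle",
    "residue_cooperativity",
    "residue_cooperativity_table",
    "round_half_away",
]

#: Thermodynamic channels tracked through the cycle.  ``gas`` is the
#: gas-phase interaction (ele + vdw); ``sol`` the total solvation (np + pb).
CHANNELS = ("e_ele", "e_vdw", "e_np", "e_pb", "e_es", "gas", "sol", "dh", "minus_t_ds", "dg")


def _channels(fes: FreeEnergySummary) -> dict[str, float]:
    return {
        "e_ele": fes.e_ele,
        "e_vdw": fes.e_vdw,
        "e_np": fes.e_np,
        "e_pb": fes.e_pb,
        "e_es": fes.e_es,
        "gas": fes.e_ele + fes.e_vdw,
        "sol": fes.e_np + fes.e_pb,
        "dh": fes.dh,
        "minus_t_ds": fes.minus_t_ds,
        "dg": fes.dg,
    }


def delta_vs_wt(wt: FreeEnergySummary, mut: FreeEnergySummary) -> dict[str, float]:
    """Per-channel perturbation ``mut - wt`` (the dd quantities)."""
    cw, cm = _channels(wt), _channels(mut)
    return {k: cm[k] - cw[k] for k in CHANNELS}


@dataclass
class CycleResult:
    """Full double-mutant cycle over all thermodynamic channels."""

    systems: dict[str, FreeEnergySummary]  # keys wt, mut_a, mut_b, double
    delta_a: dict[str, float]
    delta_b: dict[str, float]
    delta_double: dict[str, float]
    predicted_double: dict[str, float]  # WT + ddA + ddB, absolute values
    cooperativity: dict[str, float]  # calculated - predicted

    def table(self, decimals: int | None = 2) -> pd.DataFrame:
        """Cycle summary as a DataFrame (rows: systems, predicted,
        cooperativity), optionally rounded half-away-from-zero."""
        rows = {
            "WT": _channels(self.systems["wt"]),
            "mutA": _channels(self.systems["mut_a"]),
            "mutB": _channels(self.systems["mut_b"]),
            "double (predicted)": self.predicted_double,
            "double (calculated)": _channels(self.systems["double"]),
            "cooperativity": self.cooperativity,
        }
        df = pd.DataFrame(rows).T[list(CHANNELS)]
        if decimals is not None:
            df = df.map(lambda v: round_half_away(v, decimals))
        return df


def cycle(
    wt: FreeEnergySummary,
    mut_a: FreeEnergySummary,
    mut_b: FreeEnergySummary,
    double: FreeEnergySummary,
) -> CycleResult:
    """Build the double-mutant cycle from the four system summaries."""
    da = delta_vs_wt(wt, mut_a)
    db = delta_vs_wt(wt, mut_b)
    dd = delta_vs_wt(wt, double)
    cw = _channels(wt)
    predicted = {k: cw[k] + da[k] + db[k] for k in CHANNELS}
    cd = _channels(double)
    coop = {k: cd[k] - predicted[k] for k in CHANNELS}
    return CycleResult(
        systems={"wt": wt, "mut_a": mut_a, "mut_b": mut_b, "double": double},
        delta_a=da,
        delta_b=db,
        delta_double=dd,
        predicted_double=predicted,
        cooperativity=coop,
    )


def residue_cooperativity(
    wt: dict[str, float],
    mut_a: dict[str, float],
    mut_b: dict[str, float],
    double: dict[str, float],
) -> dict[str, float]:
    """Per-residue cooperativity ``double - mutA - mutB + WT``.

    Inputs map residue labels to that residue's enthalpy contribution in
    each system; all four maps must share the same labels.
    """
    labels = list(wt)
    for other in (mut_a, mut_b, double):
        if set(other) != set(labels):
            raise ValueError("all four systems must decompose over the same residues")
    return {r: double[r] - mut_a[r] - mut_b[r] + wt[r] for r in labels}


def residue_cooperativity_table(
    wt: dict[str, float],
    mut_a: dict[str, float],
    mut_b: dict[str, float],
    double: dict[str, float],
    system_names: tuple[str, str, str, str] = ("WT", "mutA", "mutB", "double"),
) -> pd.DataFrame:
    """Per-system residue contributions with a cooperativity row appended."""
    coop = residue_cooperativity(wt, mut_a, mut_b, double)
    df = pd.DataFrame(
        [wt, mut_a, mut_b, double, coop],
        index=[*system_names, "cooperativity"],
    )
    return df


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round with ties going away from zero (presentation convention for
    2-decimal thermodynamic tables)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor
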