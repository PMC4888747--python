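"""Double-mutant-cycle arithmetic on the published streptavidin-biotin tables
and on synthetic systems with known coupling."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ddgcycle.cycles import (
    CHANNELS,
    cycle,
    delta_vs_wt,
    residue_cooperativity,
    residue_cooperativity_table,
    round_half_away,
)
from ddgcycle.endstate import component_energies, summarize
from ddgcycle.published import RESIDUE_ENTHALPY, summary
from ddgcycle.synth import SynthSpec, designated_residues, make_complex, make_ensemble, make_mutant


@pytest.fixture(scope="module")
def published_cycle():
    wt, s45a, d128a, dm = (summary(k) for k in ("WT", "S45A", "D128A", "DM"))
    return cycle(wt, s45a, d128a, dm)


class TestDeltaVsWt:
    def test_published_single_mutant_perturbations(self):
        wt = summary("WT")
        assert delta_vs_wt(wt, summary("S45A"))["dg"] == pytest.approx(5.27, abs=5e-3)
        d = delta_vs_wt(wt, summary("D128A"))
        assert d["e_ele"] == pytest.approx(-25.08, abs=5e-3)
        assert d["e_pb"] == pytest.approx(32.02, abs=5e-3)

    def test_identical_summaries_all_zero(self):
        wt = summary("WT")
        assert all(v == 0.0 for v in delta_vs_wt(wt, wt).values())


class TestCycle:
    def test_published_cooperativities(self, published_cycle):
        coop = published_cycle.cooperativity
        assert coop["dg"] == pytest.approx(2.68, abs=5e-3)
        assert coop["dh"] == pytest.approx(1.54, abs=5e-3)
        assert coop["minus_t_ds"] == pytest.approx(1.14, abs=5e-3)
        assert coop["gas"] == pytest.approx(-3.92, abs=5e-3)
        assert coop["sol"] == pytest.approx(5.46, abs=5e-3)

    def test_predicted_double_is_additive(self, published_cycle):
        wt_dg = summary("WT").dg
        assert published_cycle.predicted_double["dg"] - wt_dg == pytest.approx(
            5.27 + 6.85, abs=5e-3)

    def test_channel_consistency(self, published_cycle):
        coop = published_cycle.cooperativity
        assert coop["dg"] == pytest.approx(coop["dh"] + coop["minus_t_ds"], abs=1e-10)
        assert coop["dh"] == pytest.approx(coop["gas"] + coop["sol"], abs=1e-10)

    def test_equivalent_two_step_formula(self, published_cycle):
        # coop = double - mutA - mutB + WT, channel by channel
        sy = published_cycle.systems
        from ddgcycle.cycles import _channels

        for ch in CHANNELS:
            direct = (_channels(sy["double"])[ch] - _channels(sy["mut_a"])[ch]
                      - _channels(sy["mut_b"])[ch] + _channels(sy["wt"])[ch])
            assert published_cycle.cooperativity[ch] == pytest.approx(direct, abs=1e-10)

    def test_order_invariance(self):
        wt, a, b, dm = (summary(k) for k in ("WT", "S45A", "D128A", "DM"))
        c1 = cycle(wt, a, b, dm)
        c2 = cycle(wt, b, a, dm)
        for ch in CHANNELS:
            assert c1.predicted_double[ch] == pytest.approx(c2.predicted_double[ch], abs=1e-12)
            assert c1.cooperativity[ch] == pytest.approx(c2.cooperativity[ch], abs=1e-12)

    def test_additive_synthetic_gas_phase_zero(self):
        spec = SynthSpec(n_residues=4, ligand_atoms=4, n_frames=20, seed=13)
        s, t = make_complex(spec)
        ra, rb = (r + 1 for r in designated_residues(spec))
        sa, ta = make_mutant(s, t, ra)
        sb, tb = make_mutant(s, t, rb)
        sab, tab = make_mutant(sa, ta, rb)
        summaries = []
        for st, tt in ((s, t), (sa, ta), (sb, tb), (sab, tab)):
            ens = make_ensemble(st, tt, spec)
            summaries.append(summarize(component_energies(ens, st, tt, solvation="none")))
        coop = cycle(*summaries).cooperativity
        assert abs(coop["gas"]) < 1e-8  # linearity of pair sums in the charges


class TestResidueCooperativity:
    def test_published_largest_contributors(self):
        coop = residue_cooperativity(*(RESIDUE_ENTHALPY[k]
                                       for k in ("WT", "S45A", "D128A", "DM")))
        assert coop["N49"] == pytest.approx(5.70, abs=5e-3)
        assert coop["S88"] == pytest.approx(2.43, abs=5e-3)

    def test_invariant_residue_gives_zero(self):
        base = {"R1": -3.0, "R2": 1.5}
        assert residue_cooperativity(base, base, base, base) == {"R1": 0.0, "R2": 0.0}

    def test_table_layout(self):
        df = residue_cooperativity_table(*(RESIDUE_ENTHALPY[k]
                                           for k in ("WT", "S45A", "D128A", "DM")))
        assert list(df.index)[-1] == "cooperativity"
        assert df.loc["cooperativity", "N49"] == pytest.approx(5.70, abs=5e-3)

    def test_mismatched_labels_rejected(self):
        with pytest.raises(ValueError):
            residue_cooperativity({"A": 0.0}, {"A": 0.0}, {"B": 0.0}, {"A": 0.0})


component = st.floats(min_value=-200.0, max_value=200.0,
                      allow_nan=False, allow_infinity=False)


@st.composite
def summaries(draw):
    from ddgcycle.endstate import FreeEnergySummary

    return FreeEnergySummary.from_components(
        draw(component), draw(component), draw(component), draw(component),
        minus_t_ds=draw(component))


@settings(max_examples=50, derandomize=True)
@given(summaries(), summaries(), summaries(), summaries())
def test_cycle_identities_hold_for_arbitrary_components(wt, a, b, ab):
    """Cooperativity equals the four-state alternating sum and is channel-
    additive for any component values, not just the published ones."""
    c = cycle(wt, a, b, ab)
    for ch in CHANNELS:
        direct = (c.delta_double[ch] - c.delta_a[ch] - c.delta_b[ch])
        assert c.cooperativity[ch] == pytest.approx(direct, abs=1e-9)
    assert c.cooperativity["dg"] == pytest.approx(
        c.cooperativity["dh"] + c.cooperativity["minus_t_ds"], abs=1e-9)
    assert c.cooperativity["dh"] == pytest.approx(
        c.cooperativity["gas"] + c.cooperativity["sol"], abs=1e-9)


@settings(max_examples=100, derandomize=True)
@given(st.floats(min_value=-1000.0, max_value=1000.0,
                 allow_nan=False, allow_infinity=False))
def test_round_half_away_properties(x):
    r = round_half_away(x, 2)
    assert abs(r - x) <= 0.005 + 1e-12
    assert round_half_away(-x, 2) == -r


@pytest.mark.parametrize(
    "x, expected",
    [(2.675, 2.68), (-2.675, -2.68), (1.004, 1.0), (0.125, 0.13), (-0.125, -0.13)],
)
def test_round_half_away(x, expected):
    assert round_half_away(x) == expected
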