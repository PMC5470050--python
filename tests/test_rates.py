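"""Rate-law correctness against an exact rational-arithmetic oracle, plus
the structural properties of the ordered bi-bi forms."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from alcocyte.constants import default_constants
from alcocyte.rates import (
    Concentrations,
    EnzymeLevel,
    haldane_diagnostic,
    v_adh,
    v_ald,
    v_ldh,
    vmax_from_activity,
)

from oracle import adh_rate, ald_rate, ldh_rate

KS = default_constants()
ADH = EnzymeLevel.from_activity("ADH", 1.0)
ALD = EnzymeLevel("ALD", 1.0)
LDH = EnzymeLevel.from_activity("LDH", 1.0)

conc = st.floats(min_value=0.0, max_value=1e5, allow_nan=False, allow_infinity=False)


def rel_err(a, b):
    return abs(a - b) / max(abs(b), 1e-300)


class TestAgainstOracle:
    def test_adh_frozen_example(self):
        """Saturating NAD+/ethanol, no products: exact value 3/11 per the
        rational expression."""
        c = Concentrations(nad=270, ethanol=17000)
        assert v_adh(c, KS["ADH"], ADH) == pytest.approx(3 / 11, rel=1e-12)
        assert adh_rate(270, 17000, 0, 0, 1, Fraction(340, 40)) == Fraction(3, 11)

    def test_ald_frozen_example(self):
        c = Concentrations(nad=20, acetaldehyde=9, nadh=100)
        assert v_ald(c, KS["ALD"], ALD) == pytest.approx(1 / 11, rel=1e-12)
        assert ald_rate(20, 9, 100, 1) == Fraction(1, 11)

    def test_ldh_frozen_example(self):
        c = Concentrations(nadh=8, pyruvate=120)
        expected = ldh_rate(0, 120, 8, 0, 1, Fraction(60, 550))
        assert expected == Fraction(1500, 9002)
        assert v_ldh(c, KS["LDH"], LDH) == pytest.approx(float(expected), rel=1e-12)

    def test_thousand_random_states_agree_to_1e10(self):
        """All three laws match the exact oracle to 1e-10 relative on random
        nonnegative concentration vectors."""
        rng = np.random.default_rng(12345)
        for _ in range(1000):
            x = rng.uniform(0, 1) * 10 ** rng.uniform(-2, 5, size=6)
            nad, eth, pyr, ald, nadh, lac = x
            c = Concentrations(nad=nad, ethanol=eth, pyruvate=pyr, acetaldehyde=ald, nadh=nadh, lactate=lac)
            got = v_adh(c, KS["ADH"], ADH)
            want = float(adh_rate(nad, eth, ald, nadh, 1, Fraction(340, 40)))
            assert rel_err(got, want) < 1e-10 or abs(got - want) < 1e-9
            got = v_ald(c, KS["ALD"], ALD)
            want = float(ald_rate(nad, ald, nadh, 1))
            assert rel_err(got, want) < 1e-10 or abs(got - want) < 1e-9
            got = v_ldh(c, KS["LDH"], LDH)
            want = float(ldh_rate(nad, pyr, nadh, lac, 1, Fraction(60, 550)))
            assert rel_err(got, want) < 1e-10 or abs(got - want) < 1e-9


class TestStructure:
    def test_empty_system_rates_vanish(self):
        c = Concentrations()
        assert v_adh(c, KS["ADH"], ADH) == 0
        assert v_ald(c, KS["ALD"], ALD) == 0
        assert v_ldh(c, KS["LDH"], LDH) == 0

    def test_product_only_states_force_reverse_sign(self):
        assert v_adh(Concentrations(acetaldehyde=50, nadh=10), KS["ADH"], ADH) < 0
        assert v_ldh(Concentrations(nad=50, lactate=500), KS["LDH"], LDH) < 0

    def test_ald_no_substrate_and_saturation_limit(self):
        assert v_ald(Concentrations(nad=100), KS["ALD"], ALD) == 0
        # substrates at 100x their largest constants: within 1% of Vmax
        c = Concentrations(nad=100 * 70, acetaldehyde=100 * 20)
        assert v_ald(c, KS["ALD"], ALD) == pytest.approx(1.0, rel=0.01)

    @given(
        nad=conc, ald1=conc, nadh1=conc,
        d_ald=st.floats(min_value=0, max_value=1e4),
        d_nadh=st.floats(min_value=0, max_value=1e4),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_ald_monotonicity(self, nad, ald1, nadh1, d_ald, d_nadh):
        """ALD rate is nonincreasing in NADH and nondecreasing in each
        substrate."""
        k, e = KS["ALD"], ALD
        base = v_ald(Concentrations(nad=nad, acetaldehyde=ald1, nadh=nadh1), k, e)
        more_sub = v_ald(Concentrations(nad=nad, acetaldehyde=ald1 + d_ald, nadh=nadh1), k, e)
        more_inh = v_ald(Concentrations(nad=nad, acetaldehyde=ald1, nadh=nadh1 + d_nadh), k, e)
        assert more_sub >= base - 1e-12
        assert more_inh <= base + 1e-12
        assert 0 <= base <= e.vmax_f

    @given(nad=st.floats(1.0, 1e3), eth=st.floats(1.0, 1e5), ald=st.floats(0.01, 1e3))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_reversible_rate_changes_sign_across_equilibrium_manifold(self, nad, eth, ald):
        """The net ADH rate vanishes exactly where the mass-action ratio of
        the numerator terms balances, and flips sign across that manifold."""
        k, e = KS["ADH"], ADH
        # numerator zero: vf*nad*eth/(Kia*Kb) = vr*ald*nadh/(Kp*Kiq)
        nadh_star = (e.vmax_f * nad * eth * k.k_p * k.k_iq) / (e.vmax_r * ald * k.k_ia * k.k_b)
        at = v_adh(Concentrations(nad=nad, ethanol=eth, acetaldehyde=ald, nadh=nadh_star), k, e)
        below = v_adh(Concentrations(nad=nad, ethanol=eth, acetaldehyde=ald, nadh=0.5 * nadh_star), k, e)
        above = v_adh(Concentrations(nad=nad, ethanol=eth, acetaldehyde=ald, nadh=2.0 * nadh_star), k, e)
        assert abs(at) < 1e-9 * max(abs(below), abs(above), 1e-30)
        assert below > 0 > above

    @given(lam=st.floats(0.01, 100), nad=conc, eth=conc, ald=conc, nadh=conc)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_vmax_scaling_is_exactly_linear(self, lam, nad, eth, ald, nadh):
        c = Concentrations(nad=nad, ethanol=eth, acetaldehyde=ald, nadh=nadh)
        base = v_adh(c, KS["ADH"], ADH)
        scaled = v_adh(c, KS["ADH"], ADH.scaled(lam))
        assert scaled == pytest.approx(lam * base, rel=1e-12, abs=1e-300)

    def test_rate_bounded_by_vmax(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            x = 10 ** rng.uniform(-2, 6, size=4)
            c = Concentrations(nad=x[0], ethanol=x[1], acetaldehyde=x[2], nadh=x[3])
            r = v_adh(c, KS["ADH"], ADH)
            assert abs(r) <= max(ADH.vmax_f, ADH.vmax_r) * (1 + 1e-12)

    def test_negative_concentration_names_field(self):
        with pytest.raises(ValueError, match="ethanol"):
            Concentrations(ethanol=-1.0)

    def test_wrong_constant_set_rejected(self):
        with pytest.raises(ValueError, match="expected ADH"):
            v_adh(Concentrations(), KS["LDH"], ADH)


class TestActivityConversion:
    def test_zero_activity(self):
        assert vmax_from_activity(0.0, hematocrit=0.3) == 0.0

    def test_suspension_unit_identity(self):
        """1 nkat/ml of a cell-free mixture is exactly 1 µM/s = 3.6 mmol/(l·h)."""
        assert vmax_from_activity(1.0, hematocrit=0.0) == 1.0
        assert vmax_from_activity(1.0, hematocrit=0.0) * 3.6 == pytest.approx(3.6)

    def test_per_cell_concentration(self):
        """170 nkat/ml of suspension at Hct 0.28 concentrates to
        170/0.28 µM/s of cell water (dimensional analysis)."""
        assert vmax_from_activity(170.0, hematocrit=0.28) == pytest.approx(170 / 0.28)
        assert vmax_from_activity(170.0, hematocrit=0.28, convention="packed_cells") == 170.0

    def test_packed_cells_needs_hematocrit(self):
        with pytest.raises(ValueError, match="hematocrit"):
            vmax_from_activity(1.0, hematocrit=0.0, convention="packed_cells")

    def test_reverse_vmax_follows_turnover_ratio(self):
        lvl = EnzymeLevel.from_activity("ADH", 10.0, hematocrit=0.25)
        assert lvl.vmax_r == pytest.approx(lvl.vmax_f * 340 / 40)
        assert EnzymeLevel.from_activity("ALD", 10.0, hematocrit=0.25).vmax_r is None


class TestHaldane:
    def test_exactly_consistent_set_gives_unity(self):
        k = KS["ADH"].with_overrides(k_eq=(40 * 800 * 31) / (340 * 270 * 17000))
        assert haldane_diagnostic(k)["ratio_printed"] == pytest.approx(1.0, rel=1e-12)

    def test_tabulated_sets_reported_not_enforced(self):
        """Implied kinetic Keq from the Haldane relation, by exact hand
        arithmetic: ADH 992000/1560600000, LDH 33000000/5760."""
        d = haldane_diagnostic(KS["ADH"])
        assert d["implied_keq"] == pytest.approx(float(Fraction(992000, 1560600000)), rel=1e-12)
        d = haldane_diagnostic(KS["LDH"])
        assert d["implied_keq"] == pytest.approx(float(Fraction(550 * 6000 * 100, 60 * 8 * 120)), rel=1e-12)
        assert {"ratio_printed", "ratio_molar"} <= d.keys()

    def test_irreversible_enzyme_unsupported(self):
        with pytest.raises(ValueError, match="irreversible"):
            haldane_diagnostic(KS["ALD"])
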