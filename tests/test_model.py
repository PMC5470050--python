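"""Dynamical-system tests: derivative balances, conservation integrals,
reduction equivalence, and integrator convergence."""

import dataclasses

import numpy as np
import pytest

from alcocyte.model import (
    ExperimentConfig,
    ModelState,
    PyruvateRegime,
    conserved_residuals,
    derivatives,
    integrate,
    integrate_reduced,
)
from alcocyte.rates import EnzymeLevel

from conftest import make_enzymes


def test_no_enzymes_gives_constant_course():
    cfg = ExperimentConfig(
        enzymes=make_enzymes(0.0, 0.0, 0.0),
        hematocrit=0.25,
        nad0_uM=40.0,
        ethanol0_mM=10.0,
        pyruvate_regime=PyruvateRegime.bolus(initial_mM=1.0),
        duration_h=5.0,
    )
    tc = integrate(cfg)
    for col in ("ethanol_mM", "nad_uM", "pyruvate_uM", "acetaldehyde_uM"):
        assert np.allclose(tc.data[col], tc.data[col].iloc[0], atol=1e-12)
    res = conserved_residuals(tc, cfg.conserved_totals())
    assert res["nad"] == 0.0 and res["alcohol_mass"] < 1e-15


def test_zero_derivative_without_enzymes_or_influx(small_config):
    cfg = dataclasses.replace(small_config, enzymes=make_enzymes(0.0, 0.0, 0.0))
    d = derivatives(cfg.initial_state(), cfg)
    assert all(
        getattr(d, f) == 0.0 for f in ("nad", "ethanol", "pyruvate", "acetaldehyde", "lactate", "acetate")
    )


def test_derivatives_match_euler_step_oracle(small_config):
    """A tiny explicit Euler step of the integrated trajectory agrees with
    the reported derivative to first order."""
    cfg = small_config
    state = ModelState(nad=30.0, ethanol=8.0, pyruvate=400.0, acetaldehyde=5.0, lactate=50.0)
    d = derivatives(state, cfg)
    h = 1e-8  # hours; the system is stiff, so the step must be tiny
    grid = np.array([0.0, h])
    cfg2 = cfg.with_(
        nadh0_uM=cfg.nad0_uM - state.nad,
        ethanol0_mM=state.ethanol,
        pyruvate_regime=PyruvateRegime.bolus(initial_uM=state.pyruvate),
        acetaldehyde0_uM=state.acetaldehyde,
        lactate0_uM=state.lactate,
        duration_h=h,
        sampling_grid_h=grid,
        rtol=1e-13,
        atol=1e-13,
    )
    tc = integrate(cfg2)
    step_eth = (tc.data.ethanol_mM.iloc[1] - tc.data.ethanol_mM.iloc[0]) / h
    step_nad = (tc.data.nad_uM.iloc[1] - tc.data.nad_uM.iloc[0]) / h
    assert step_eth == pytest.approx(d.ethanol, rel=1e-3)
    assert step_nad == pytest.approx(d.nad, rel=1e-3)


def test_nad_nadh_balance_is_structural(small_config):
    """NADH is derived as NAD0 - NAD, so the pool is conserved exactly."""
    tc = integrate(small_config)
    total = tc.data.nad_uM + tc.data.nadh_uM
    assert np.all(total == small_config.nad0_uM)


def test_conservation_residuals_below_1e6(small_config, clamp_config):
    for cfg in (small_config, clamp_config):
        res = integrate(cfg).meta["residuals"]
        assert res["nad"] <= 1e-6 and res["alcohol_mass"] <= 1e-6
        if res["c0_applicable"]:
            assert res["c0"] <= 1e-6 and res["pyr_lac"] <= 1e-6


def test_c0_drift_under_influx_matches_quadrature(small_config):
    """With a pyruvate source the combined integral drifts by exactly
    -integral(V_in dt)."""
    vin = 3.0  # mmol/l_RBCs/h
    cfg = small_config.with_(pyruvate_regime=PyruvateRegime.influx(vin_mmol_per_l_rbc_h=vin))
    tc = integrate(cfg)
    drift = tc.meta["residuals"]["c0_drift_uM"]
    expected = -vin * cfg.hematocrit * 1e3 * tc.time_h  # µM, suspension scale
    assert np.allclose(drift, expected, rtol=1e-6, atol=1e-6)


def test_three_variable_reduction_equivalent_at_zero_influx(small_config):
    """The classical closure through the conservation integrals reproduces
    the four-variable trajectories when V_in = 0."""
    cfg = small_config.with_(rtol=1e-11, atol=1e-12)
    full = integrate(cfg).data
    reduced = integrate_reduced(cfg).data
    for col in ("ethanol_mM", "nad_uM", "pyruvate_uM", "acetaldehyde_uM"):
        scale = max(np.max(np.abs(full[col])), 1.0)
        assert np.max(np.abs(full[col] - reduced[col])) / scale < 1e-8


def test_reduction_refuses_pyruvate_sources(clamp_config):
    with pytest.raises(ValueError, match="sourceless"):
        integrate_reduced(clamp_config)


def test_ethanol_monotone_when_reverse_flux_negligible(small_config):
    tc = integrate(small_config)
    assert np.all(np.diff(tc.ethanol_mM) <= 1e-12)
    assert (tc.data.drop(columns="time_h") >= -1e-9).all().all()


def test_tolerance_refinement_convergence(small_config):
    """10x tighter tolerances change sampled concentrations by < 1e-5
    relative."""
    coarse = integrate(small_config).data
    fine = integrate(small_config.with_(rtol=1e-9, atol=1e-11)).data
    for col in ("ethanol_mM", "nad_uM", "pyruvate_uM", "acetaldehyde_uM"):
        scale = max(np.max(np.abs(fine[col])), 1e-6)
        assert np.max(np.abs(coarse[col] - fine[col])) / scale < 1e-5


def test_enzyme_doubling_doubles_initial_rate_at_clamped_cofactors():
    """With NAD+ in large excess and pyruvate clamped, the flux is linear in
    total enzyme."""
    hct = 0.25
    base = ExperimentConfig(
        enzymes=make_enzymes(5.0, 50.0, 100.0, hct),  # ADH-limited: product pools equilibrate fast
        hematocrit=hct,
        nad0_uM=5000.0,
        ethanol0_mM=20.0,
        pyruvate_regime=PyruvateRegime.clamp(target_uM=1000.0),
        duration_h=0.02,
        sampling_grid_h=np.linspace(0.004, 0.02, 9),  # past the start-up transient, before products accumulate
    )
    doubled = base.with_(enzymes={k: v.scaled(2.0) for k, v in base.enzymes.items()})
    def rate(cfg):
        tc = integrate(cfg)
        return -np.polyfit(tc.time_h, tc.ethanol_mM, 1)[0]
    assert rate(doubled) == pytest.approx(2 * rate(base), rel=5e-3)


def test_ald_excess_and_high_nad_reach_adh_limit():
    """With ALD overwhelming and the cofactor pool clamped high, ethanol
    decline approaches the ADH-limited saturation rate."""
    from alcocyte.rates import Concentrations, v_adh
    from alcocyte.constants import default_constants

    hct = 0.25
    adh_level = EnzymeLevel.from_activity("ADH", 20.0, hematocrit=hct)
    cfg = ExperimentConfig(
        enzymes={
            "ADH": adh_level,
            "ALD": EnzymeLevel.from_activity("ALD", 20000.0, hematocrit=hct),
            "LDH": EnzymeLevel.from_activity("LDH", 20000.0, hematocrit=hct),
        },
        hematocrit=hct,
        nad0_uM=50000.0,
        ethanol0_mM=20.0,
        pyruvate_regime=PyruvateRegime.clamp(target_uM=10000.0),
        duration_h=0.1,
        sampling_grid_h=np.linspace(0, 0.1, 11),
    )
    tc = integrate(cfg)
    # closed-form ADH forward rate at the initial state, products ~ 0
    c = Concentrations(nad=50000.0, ethanol=20000.0)
    v_limit = v_adh(c, default_constants()["ADH"], adh_level)  # µM/s cell scale
    observed = -np.polyfit(tc.time_h, 1e3 * tc.ethanol_mM, 1)[0] / 3600.0 / hct
    assert observed == pytest.approx(v_limit, rel=0.05)


def test_clamp_holds_pyruvate_exactly(clamp_config):
    tc = integrate(clamp_config)
    assert np.all(tc.data.pyruvate_uM == 100.0)
    assert np.all(np.diff(tc.data.lactate_uM) >= 0)


def test_config_validation_errors():
    enz = make_enzymes()
    good = dict(
        enzymes=enz, hematocrit=0.25, nad0_uM=40.0, ethanol0_mM=10.0, duration_h=1.0
    )
    with pytest.raises(ValueError, match="hematocrit"):
        ExperimentConfig(**{**good, "hematocrit": 1.5})
    with pytest.raises(ValueError, match="nadh0"):
        ExperimentConfig(**{**good, "nadh0_uM": 50.0})
    with pytest.raises(ValueError, match="increasing"):
        ExperimentConfig(**{**good, "sampling_grid_h": np.array([0.0, 0.5, 0.4])})
    with pytest.raises(ValueError, match="influx"):
        ExperimentConfig(
            **{**good, "hematocrit": 0.0,
               "pyruvate_regime": PyruvateRegime.influx(vin_mmol_per_l_rbc_h=1.0)}
        )
    with pytest.raises(ValueError, match="missing enzyme"):
        ExperimentConfig(**{**good, "enzymes": {"ADH": enz["ADH"]}})
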