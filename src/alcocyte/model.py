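"""The alcocyte dynamical system and its integration.

The model couples the three dehydrogenase rate laws through a conserved
NAD+/NADH pool and a pyruvate pool:

    d(Alc)/dt  = -V_ADH
    d(Ald)/dt  =  V_ADH - V_ALD
    d(Acet)/dt =  V_ALD
    d(NAD)/dt  = -V_ADH - V_ALD + V_LDH      (NADH = NAD0 - NAD)
    d(Pyr)/dt  = -V_LDH + V_in
    d(Lac)/dt  =  V_LDH

Compartment bookkeeping: the cofactor pool (NAD+/NADH) is intracellular and
expressed at cell-water scale, while ethanol, pyruvate, acetaldehyde,
lactate and acetate are treated as one rapidly equilibrating pool expressed
at suspension scale (molar concentrations are equal across the membrane, so
the rate laws can be fed suspension-scale values directly).  Reaction
fluxes, evaluated at cell scale, drain the suspension pool scaled by
hematocrit.  A cell-free system (hematocrit 0) collapses to a single
compartment.

The four chemical degrees of freedom (NAD+, ethanol, acetaldehyde,
pyruvate) are integrated directly, with lactate and acetate as quadratures;
the classical three-variable reduction through the conservation integrals
(valid only when V_in = 0) is kept as a verified special case, see
:func:`integrate_reduced`.

Units: hours and mM/µM externally, seconds and µM internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .constants import KineticConstants, default_constants
from .rates import Concentrations, EnzymeLevel, v_adh, v_ald, v_ldh

__all__ = [
    "PyruvateRegime",
    "ExperimentConfig",
    "ModelState",
    "ConservedTotals",
    "TimeCourse",
    "IntegrationError",
    "derivatives",
    "integrate",
    "integrate_reduced",
    "conserved_residuals",
]

_SECONDS_PER_HOUR = 3600.0


class IntegrationError(RuntimeError):
    """Raised when the stiff solver fails; carries the last valid state."""

    def __init__(self, message: str, last_time_h: float, last_state: np.ndarray):
        super().__init__(
            f"{message} (last valid state at t={last_time_h:.4g} h; "
            "consider loosening rtol/atol by 10x or shortening the duration)"
        )
        self.last_time_h = last_time_h
        self.last_state = last_state


@dataclass(frozen=True)
class PyruvateRegime:
    """Exactly one of the four pyruvate supply regimes.

    - ``none``: no exogenous pyruvate, no influx.
    - ``bolus``: a single initial addition (µM, suspension scale).
    - ``clamp``: concentration held constant at a target (µM), emulating a
      micropump feed; implemented as an algebraic hold (d(Pyr)/dt = 0).
    - ``influx``: constant production at ``vin`` mmol/(l_RBCs·h), the
      glycolysis / membrane-transport surrogate.
    """

    kind: str = "none"
    value: float = 0.0

    _KINDS = ("none", "bolus", "clamp", "influx")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown pyruvate regime {self.kind!r}; expected one of {self._KINDS}")
        if self.value < 0:
            raise ValueError("pyruvate regime value must be nonnegative")

    @classmethod
    def none(cls) -> "PyruvateRegime":
        return cls("none", 0.0)

    @classmethod
    def bolus(cls, *, initial_uM: float | None = None, initial_mM: float | None = None) -> "PyruvateRegime":
        if (initial_uM is None) == (initial_mM is None):
            raise ValueError("specify exactly one of initial_uM / initial_mM")
        return cls("bolus", initial_uM if initial_uM is not None else 1000.0 * initial_mM)

    @classmethod
    def clamp(cls, *, target_uM: float) -> "PyruvateRegime":
        return cls("clamp", target_uM)

    @classmethod
    def influx(cls, *, vin_mmol_per_l_rbc_h: float) -> "PyruvateRegime":
        return cls("influx", vin_mmol_per_l_rbc_h)


@dataclass(frozen=True)
class ModelState:
    """Instantaneous model state in external units.

    ``nad`` (µM, cell scale) is the oxidized cofactor; NADH is always derived
    as ``nad0 - nad``, never stored.  ``ethanol``/``acetate`` are mM and
    ``pyruvate``/``acetaldehyde``/``lactate`` µM, all at suspension scale.
    """

    nad: float
    ethanol: float
    pyruvate: float
    acetaldehyde: float
    lactate: float = 0.0
    acetate: float = 0.0
    time: float = 0.0


@dataclass(frozen=True)
class ConservedTotals:
    """The conservation integrals of the dynamical system.

    ``nad0`` µM (cell scale); ``alc0`` mM; ``pyr0`` µM; ``c0`` µM in
    suspension equivalents: ``c0 = 2*Alc + Ald - Pyr - phi*NAD`` at t=0,
    where ``phi`` is the hematocrit (1 for cell-free).  ``pyr0`` and ``c0``
    are first integrals only when there is no pyruvate source (V_in = 0, no
    clamp).
    """

    nad0: float
    alc0: float
    pyr0: float
    c0: float


@dataclass(frozen=True)
class ExperimentConfig:
    """One simulated experiment.

    ``enzymes`` maps ADH/ALD/LDH to :class:`EnzymeLevel` objects whose Vmax
    is already at reacting-compartment (cell-water) scale.  ``nad0_uM`` is
    the total intracellular cofactor pool; ``nadh0_uM`` the initially
    reduced part.  ``hematocrit=0`` selects a cell-free, single-compartment
    system.
    """

    enzymes: Mapping[str, EnzymeLevel]
    hematocrit: float
    nad0_uM: float
    ethanol0_mM: float
    pyruvate_regime: PyruvateRegime = field(default_factory=PyruvateRegime.none)
    nadh0_uM: float = 0.0
    acetaldehyde0_uM: float = 0.0
    lactate0_uM: float = 0.0
    acetate0_mM: float = 0.0
    duration_h: float = 5.0
    sampling_grid_h: np.ndarray | None = None
    constants: Mapping[str, KineticConstants] | None = None
    rtol: float = 1e-8
    atol: float = 1e-10

    def __post_init__(self) -> None:
        for enz in ("ADH", "ALD", "LDH"):
            if enz not in self.enzymes:
                raise ValueError(f"missing enzyme level for {enz}")
        if not 0 <= self.hematocrit < 1:
            raise ValueError("hematocrit must lie in [0, 1)")
        if self.nad0_uM < 0 or self.nadh0_uM < 0 or self.nadh0_uM > self.nad0_uM:
            raise ValueError("need 0 <= nadh0_uM <= nad0_uM")
        if self.ethanol0_mM < 0:
            raise ValueError("ethanol0_mM must be nonnegative")
        if self.duration_h <= 0:
            raise ValueError("duration_h must be positive")
        if self.pyruvate_regime.kind == "influx" and self.hematocrit == 0:
            raise ValueError("influx regime is defined per liter of RBCs; needs hematocrit > 0")
        grid = self.grid_h
        if grid.ndim != 1 or len(grid) < 2:
            raise ValueError("sampling grid needs at least two time points")
        if not (np.all(np.diff(grid) > 0) and grid[0] >= 0 and grid[-1] <= self.duration_h):
            raise ValueError("sampling times must be strictly increasing within [0, duration]")

    @property
    def grid_h(self) -> np.ndarray:
        if self.sampling_grid_h is not None:
            return np.asarray(self.sampling_grid_h, dtype=float)
        # default: fine uniform grid, ~36 s spacing
        return np.linspace(0.0, self.duration_h, int(round(self.duration_h * 100)) + 1)

    @property
    def phi(self) -> float:
        """Compartment scale factor: hematocrit, or 1 for cell-free."""
        return self.hematocrit if self.hematocrit > 0 else 1.0

    def constants_for(self, enzyme_id: str) -> KineticConstants:
        if self.constants is not None and enzyme_id in self.constants:
            return self.constants[enzyme_id]
        return default_constants()[enzyme_id]

    def initial_state(self) -> ModelState:
        pyr0 = self.pyruvate_regime.value if self.pyruvate_regime.kind in ("bolus", "clamp") else 0.0
        return ModelState(
            nad=self.nad0_uM - self.nadh0_uM,
            ethanol=self.ethanol0_mM,
            pyruvate=pyr0,
            acetaldehyde=self.acetaldehyde0_uM,
            lactate=self.lactate0_uM,
            acetate=self.acetate0_mM,
            time=0.0,
        )

    def conserved_totals(self) -> ConservedTotals:
        s = self.initial_state()
        c0 = 2e3 * s.ethanol + s.acetaldehyde - s.pyruvate - self.phi * s.nad
        return ConservedTotals(nad0=self.nad0_uM, alc0=self.ethanol0_mM + (s.acetaldehyde + 1e3 * s.acetate) / 1e3, pyr0=s.pyruvate + s.lactate, c0=c0)

    def with_(self, **kwargs) -> "ExperimentConfig":
        return replace(self, **kwargs)


# state vector layout (internal, µM, seconds)
_NAD, _ETH, _PYR, _ALD, _LAC, _ACE = range(6)


def _rates(y: np.ndarray, config: ExperimentConfig) -> tuple[float, float, float]:
    """Cell-scale reaction rates (µM/s) at internal state ``y``."""
    nad = min(max(y[_NAD], 0.0), config.nad0_uM)
    nadh = config.nad0_uM - nad
    pyr = config.pyruvate_regime.value if config.pyruvate_regime.kind == "clamp" else max(y[_PYR], 0.0)
    c = Concentrations(
        nad=nad,
        ethanol=max(y[_ETH], 0.0),
        pyruvate=pyr,
        acetaldehyde=max(y[_ALD], 0.0),
        nadh=nadh,
        lactate=max(y[_LAC], 0.0),
    )
    v1 = v_adh(c, config.constants_for("ADH"), config.enzymes["ADH"])
    v2 = v_ald(c, config.constants_for("ALD"), config.enzymes["ALD"])
    v3 = v_ldh(c, config.constants_for("LDH"), config.enzymes["LDH"])
    return v1, v2, v3


def _rhs(t: float, y: np.ndarray, config: ExperimentConfig) -> np.ndarray:
    v1, v2, v3 = _rates(y, config)
    phi = config.phi
    dy = np.empty(6)
    dy[_NAD] = -v1 - v2 + v3
    dy[_ETH] = -phi * v1
    dy[_ALD] = phi * (v1 - v2)
    dy[_ACE] = phi * v2
    dy[_LAC] = phi * v3
    regime = config.pyruvate_regime
    if regime.kind == "clamp":
        dy[_PYR] = 0.0
    elif regime.kind == "influx":
        # mmol/(l_RBCs·h) -> µM/s at suspension scale
        vin = regime.value * config.hematocrit * 1000.0 / _SECONDS_PER_HOUR
        dy[_PYR] = -phi * v3 + vin
    else:
        dy[_PYR] = -phi * v3
    return dy


def _state_to_y(s: ModelState) -> np.ndarray:
    return np.array([s.nad, 1e3 * s.ethanol, s.pyruvate, s.acetaldehyde, s.lactate, 1e3 * s.acetate])


def derivatives(state: ModelState, config: ExperimentConfig) -> ModelState:
    """Time derivative of ``state`` in external units per hour."""
    dy = _rhs(state.time * _SECONDS_PER_HOUR, _state_to_y(state), config) * _SECONDS_PER_HOUR
    return ModelState(
        nad=dy[_NAD],
        ethanol=dy[_ETH] / 1e3,
        pyruvate=dy[_PYR],
        acetaldehyde=dy[_ALD],
        lactate=dy[_LAC],
        acetate=dy[_ACE] / 1e3,
        time=1.0,
    )


@dataclass
class TimeCourse:
    """Sampled concentrations on a time grid.

    ``data`` columns: ``time_h``, ``ethanol_mM``, ``nad_uM``, ``nadh_uM``,
    ``pyruvate_uM``, ``acetaldehyde_uM``, ``lactate_uM``, ``acetate_mM``.
    ``meta`` carries the conservation residuals, integrator statistics and —
    for synthetic data — the noise model, seed and latent truth.
    """

    data: pd.DataFrame
    config: ExperimentConfig | None = None
    meta: dict = field(default_factory=dict)

    COLUMNS = (
        "time_h",
        "ethanol_mM",
        "nad_uM",
        "nadh_uM",
        "pyruvate_uM",
        "acetaldehyde_uM",
        "lactate_uM",
        "acetate_mM",
    )

    def __post_init__(self) -> None:
        missing = [c for c in ("time_h", "ethanol_mM") if c not in self.data.columns]
        if missing:
            raise ValueError(f"time course is missing required columns {missing}")

    @property
    def time_h(self) -> np.ndarray:
        return self.data["time_h"].to_numpy()

    @property
    def ethanol_mM(self) -> np.ndarray:
        return self.data["ethanol_mM"].to_numpy()


def integrate(config: ExperimentConfig) -> TimeCourse:
    """Integrate the alcocyte system on the config's sampling grid.

    Uses an adaptive stiff solver (LSODA) at the config's tolerances and
    attaches the conservation residuals to ``meta['residuals']``.
    """
    y0 = _state_to_y(config.initial_state())
    t_end = config.duration_h * _SECONDS_PER_HOUR
    t_eval = config.grid_h * _SECONDS_PER_HOUR
    sol = solve_ivp(
        _rhs,
        (0.0, t_end),
        y0,
        args=(config,),
        method="LSODA",
        rtol=config.rtol,
        atol=config.atol,
        t_eval=t_eval,
        dense_output=False,
    )
    if not sol.success:
        last = sol.y[:, -1] if sol.y.size else y0
        last_t = sol.t[-1] / _SECONDS_PER_HOUR if sol.t.size else 0.0
        raise IntegrationError(f"integrator failed: {sol.message}", last_t, last)
    nad = np.clip(sol.y[_NAD], 0.0, config.nad0_uM)
    data = pd.DataFrame(
        {
            "time_h": config.grid_h,  # sol.t is exactly grid*3600; avoid ulp drift
            "ethanol_mM": sol.y[_ETH] / 1e3,
            "nad_uM": nad,
            "nadh_uM": config.nad0_uM - nad,
            "pyruvate_uM": (
                np.full_like(sol.t, config.pyruvate_regime.value)
                if config.pyruvate_regime.kind == "clamp"
                else sol.y[_PYR]
            ),
            "acetaldehyde_uM": sol.y[_ALD],
            "lactate_uM": sol.y[_LAC],
            "acetate_mM": sol.y[_ACE] / 1e3,
        }
    )
    tc = TimeCourse(data=data, config=config, meta={"nfev": int(sol.nfev)})
    tc.meta["residuals"] = conserved_residuals(tc, config.conserved_totals())
    return tc


def conserved_residuals(tc: TimeCourse, totals: ConservedTotals) -> dict:
    """Maximum relative drift of each conservation integral over a course.

    The NAD and alcohol-mass integrals always apply.  The ``pyr_lac`` and
    ``c0`` integrals are first integrals only without a pyruvate source;
    the returned dict flags applicability, and for influx runs reports the
    signed ``c0`` drift (which should match ``-∫V_in dt``).
    """
    cfg = tc.config
    d = tc.data
    phi = cfg.phi if cfg is not None else 1.0
    nad_resid = float(np.max(np.abs((d["nad_uM"] + d["nadh_uM"]) - totals.nad0)) / max(totals.nad0, 1.0))
    alc = d["ethanol_mM"] + d["acetaldehyde_uM"] / 1e3 + d["acetate_mM"]
    alc_resid = float(np.max(np.abs(alc - totals.alc0)) / max(totals.alc0, 1e-12))
    out = {"nad": nad_resid, "alcohol_mass": alc_resid}
    sourceless = cfg is None or cfg.pyruvate_regime.kind in ("none", "bolus")
    out["pyr_lac_applicable"] = out["c0_applicable"] = bool(sourceless)
    pyr_lac = d["pyruvate_uM"] + d["lactate_uM"]
    c0 = 2e3 * d["ethanol_mM"] + d["acetaldehyde_uM"] - d["pyruvate_uM"] - phi * d["nad_uM"]
    scale = max(abs(totals.c0), 1.0)
    if sourceless:
        out["pyr_lac"] = float(np.max(np.abs(pyr_lac - totals.pyr0)) / max(totals.pyr0, 1.0))
        out["c0"] = float(np.max(np.abs(c0 - totals.c0)) / scale)
    else:
        out["c0_drift_uM"] = (c0 - totals.c0).to_numpy()
    return out


def integrate_reduced(config: ExperimentConfig) -> TimeCourse:
    """Three-variable closure (NAD+, ethanol, pyruvate) via the conservation
    integrals, valid only when there is no pyruvate source.

    Acetaldehyde is recovered algebraically as ``C0 + phi*NAD + Pyr - 2*Alc``
    (suspension scale) and lactate as ``Pyr0 - Pyr``.  Kept as an
    equivalence oracle for the four-variable integration.
    """
    if config.pyruvate_regime.kind not in ("none", "bolus"):
        raise ValueError("the three-variable reduction requires a sourceless pyruvate regime")
    totals = config.conserved_totals()
    phi = config.phi

    def rhs3(t: float, y: np.ndarray) -> np.ndarray:
        nad, eth, pyr = y
        ald = totals.c0 + phi * min(max(nad, 0.0), config.nad0_uM) + max(pyr, 0.0) - 2.0 * max(eth, 0.0)
        yfull = np.array([nad, eth, pyr, ald, totals.pyr0 - pyr, 0.0])
        v1, v2, v3 = _rates(yfull, config)
        return np.array([-v1 - v2 + v3, -phi * v1, -phi * v3])

    s0 = config.initial_state()
    y0 = np.array([s0.nad, 1e3 * s0.ethanol, s0.pyruvate])
    t_eval = config.grid_h * _SECONDS_PER_HOUR
    sol = solve_ivp(
        rhs3,
        (0.0, config.duration_h * _SECONDS_PER_HOUR),
        y0,
        method="LSODA",
        rtol=config.rtol,
        atol=config.atol,
        t_eval=t_eval,
    )
    if not sol.success:
        raise IntegrationError(f"integrator failed: {sol.message}", float(sol.t[-1]) / 3600.0, sol.y[:, -1])
    nad = np.clip(sol.y[0], 0.0, config.nad0_uM)
    eth = sol.y[1]
    pyr = sol.y[2]
    ald = totals.c0 + phi * nad + pyr - 2.0 * eth
    acet_mM = totals.alc0 - eth / 1e3 - ald / 1e3
    data = pd.DataFrame(
        {
            "time_h": config.grid_h,
            "ethanol_mM": eth / 1e3,
            "nad_uM": nad,
            "nadh_uM": config.nad0_uM - nad,
            "pyruvate_uM": pyr,
            "acetaldehyde_uM": ald,
            "lactate_uM": totals.pyr0 - pyr,
            "acetate_mM": acet_mM,
        }
    )
    return TimeCourse(data=data, config=config, meta={"nfev": int(sol.nfev), "reduced": True})
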