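"""Rate laws for ADH, ALD, and LDH, and activity-to-Vmax conversion.

All concentrations are µM and all rates µM/s *in the reacting compartment*
(cell water for loaded erythrocytes, the whole mixture for a cell-free
system).  ADH and LDH are reversible ordered bi-bi rational rate laws; ALD
is irreversible ordered bi-bi with dead-end NADH inhibition.

Sign conventions:

- ``v_adh`` > 0 means net ethanol -> acetaldehyde (NAD+ reduction),
- ``v_ald`` >= 0 always (acetaldehyde -> acetate),
- ``v_ldh`` > 0 means net pyruvate + NADH -> lactate + NAD+.
"""

from __future__ import annotations

from dataclasses import dataclass

from .constants import KineticConstants, default_constants

__all__ = [
    "Concentrations",
    "EnzymeLevel",
    "v_adh",
    "v_ald",
    "v_ldh",
    "vmax_from_activity",
    "haldane_diagnostic",
    "NKAT_PER_ML_TO_UM_PER_S",
    "UM_PER_S_TO_MMOL_L_H",
]

#: 1 nkat/ml = 1 nmol/(s·ml) = 1 µmol/(s·l) = 1 µM/s (at the scale the
#: activity is expressed in).
NKAT_PER_ML_TO_UM_PER_S = 1.0
#: 1 µM/s = 3.6 mmol/(l·h)
UM_PER_S_TO_MMOL_L_H = 3.6


@dataclass(frozen=True)
class Concentrations:
    """Instantaneous metabolite concentrations (µM), all nonnegative."""

    nad: float = 0.0
    ethanol: float = 0.0
    pyruvate: float = 0.0
    acetaldehyde: float = 0.0
    nadh: float = 0.0
    lactate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("nad", "ethanol", "pyruvate", "acetaldehyde", "nadh", "lactate"):
            if getattr(self, name) < 0:
                raise ValueError(f"concentration {name!r} must be nonnegative, got {getattr(self, name)}")


@dataclass(frozen=True)
class EnzymeLevel:
    """A catalytic activity expressed as maximal rates in model units.

    ``vmax_f`` (and ``vmax_r`` for reversible enzymes) are µM/s at the scale
    of the reacting compartment.  For reversible enzymes the reverse maximum
    is tied to the forward one through the turnover-number ratio
    (``kcat_r / kcat_f``), because only forward activities are measured.
    """

    enzyme_id: str
    vmax_f: float
    vmax_r: float | None = None

    def __post_init__(self) -> None:
        if self.vmax_f < 0:
            raise ValueError("vmax_f must be nonnegative")
        if self.vmax_r is not None and self.vmax_r < 0:
            raise ValueError("vmax_r must be nonnegative")

    @classmethod
    def from_activity(
        cls,
        enzyme_id: str,
        activity: float,
        *,
        hematocrit: float = 0.0,
        constants: KineticConstants | None = None,
        convention: str = "suspension",
    ) -> "EnzymeLevel":
        """Build from a measured catalytic activity.

        ``activity`` is in nkat per ml of suspension (``convention=
        "suspension"``, how enzymes are dosed into a suspension) or nkat per
        ml of packed cells (``convention="packed_cells"``, how loading
        studies report encapsulated activity).  The result is the Vmax seen
        in the reacting compartment: a suspension-scale activity is
        concentrated into the cell-water fraction by dividing by hematocrit.
        With ``hematocrit=0`` (cell-free) both conventions coincide.
        """
        vmax_f = vmax_from_activity(activity, hematocrit=hematocrit, convention=convention)
        if constants is None:
            constants = default_constants()[enzyme_id]
        if constants.reversible:
            vmax_r = vmax_f * constants.kcat_r / constants.kcat_f
        else:
            vmax_r = None
        return cls(enzyme_id=enzyme_id, vmax_f=vmax_f, vmax_r=vmax_r)

    def scaled(self, factor: float) -> "EnzymeLevel":
        return EnzymeLevel(
            self.enzyme_id,
            self.vmax_f * factor,
            None if self.vmax_r is None else self.vmax_r * factor,
        )


def vmax_from_activity(
    activity: float, *, hematocrit: float = 0.0, convention: str = "suspension"
) -> float:
    """Convert a catalytic activity (nkat/ml) to a compartment Vmax (µM/s).

    ``convention="suspension"``: activity per ml of suspension; enzyme is
    confined to the cells, so the cell-water Vmax is ``activity/hematocrit``
    (identity when ``hematocrit=0``, i.e. cell-free).
    ``convention="packed_cells"``: activity already per ml of cells; the
    identity 1 nkat/ml = 1 µM/s applies directly.
    """
    if activity < 0:
        raise ValueError("activity must be nonnegative")
    if not 0 <= hematocrit <= 1:
        raise ValueError("hematocrit must lie in [0, 1]")
    if convention == "suspension":
        if hematocrit == 0:
            return activity * NKAT_PER_ML_TO_UM_PER_S
        return activity * NKAT_PER_ML_TO_UM_PER_S / hematocrit
    if convention == "packed_cells":
        if hematocrit == 0:
            raise ValueError("packed_cells convention requires hematocrit > 0")
        return activity * NKAT_PER_ML_TO_UM_PER_S
    raise ValueError(f"unknown convention {convention!r}")


def _require(k: KineticConstants, enzyme_id: str, *names: str) -> None:
    if k.enzyme_id != enzyme_id:
        raise ValueError(f"expected {enzyme_id} constants, got {k.enzyme_id}")
    for name in names:
        if getattr(k, name) is None:
            raise ValueError(f"{enzyme_id}: missing constant {name!r}")


def v_adh(c: Concentrations, k: KineticConstants, e: EnzymeLevel) -> float:
    """Net ADH rate (µM/s); positive consumes ethanol and NAD+.

    Reversible ordered bi-bi in NAD+ (a), ethanol (b), acetaldehyde (p),
    NADH (q).
    """
    _require(k, "ADH", "k_a", "k_b", "k_p", "k_q", "k_ia", "k_ib", "k_ip", "k_iq")
    if e.enzyme_id != "ADH" or e.vmax_r is None:
        raise ValueError("v_adh needs an ADH EnzymeLevel with a reverse Vmax")
    a, b, p, q = c.nad, c.ethanol, c.acetaldehyde, c.nadh
    num = e.vmax_f * a * b / (k.k_ia * k.k_b) - e.vmax_r * p * q / (k.k_p * k.k_iq)
    den = (
        1.0
        + a / k.k_ia
        + b * k.k_a / (k.k_ia * k.k_b)
        + p * k.k_q / (k.k_iq * k.k_p)
        + q / k.k_iq
        + a * b / (k.k_ia * k.k_b)
        + a * p * k.k_q / (k.k_ia * k.k_p * k.k_iq)
        + b * q * k.k_a / (k.k_ia * k.k_b * k.k_iq)
        + p * q / (k.k_p * k.k_iq)
        + a * b * p / (k.k_ia * k.k_b * k.k_ip)
        + b * p * q / (k.k_ib * k.k_p * k.k_iq)
    )
    return num / den


def v_ald(c: Concentrations, k: KineticConstants, e: EnzymeLevel) -> float:
    """ALD rate (µM/s, >= 0): irreversible ordered bi-bi in NAD+ (a) and
    acetaldehyde (b) with dead-end NADH inhibition via ``k_iq``."""
    _require(k, "ALD", "k_a", "k_b", "k_ia", "k_iq")
    if e.enzyme_id != "ALD":
        raise ValueError("v_ald needs an ALD EnzymeLevel")
    a, b, q = c.nad, c.acetaldehyde, c.nadh
    num = e.vmax_f * a * b
    den = a * b + a * k.k_b + (b * k.k_a + k.k_ia * k.k_b) * (1.0 + q / k.k_iq)
    return num / den


def v_ldh(c: Concentrations, k: KineticConstants, e: EnzymeLevel) -> float:
    """Net LDH rate (µM/s); positive consumes pyruvate and NADH, regenerating
    NAD+.  Reversible ordered bi-bi in NADH (a), pyruvate (b), lactate (p),
    NAD+ (q)."""
    _require(k, "LDH", "k_a", "k_b", "k_p", "k_q", "k_ia", "k_ib", "k_ip", "k_iq")
    if e.enzyme_id != "LDH" or e.vmax_r is None:
        raise ValueError("v_ldh needs an LDH EnzymeLevel with a reverse Vmax")
    a, b, p, q = c.nadh, c.pyruvate, c.lactate, c.nad
    num = e.vmax_f * a * b / (k.k_ia * k.k_b) - e.vmax_r * p * q / (k.k_p * k.k_iq)
    den = (
        1.0
        + a / k.k_ia
        + b * k.k_a / (k.k_ia * k.k_b)
        + a * k.k_q / (k.k_iq * k.k_p)
        + q / k.k_iq
        + a * b / (k.k_ia * k.k_b)
        + a * p * k.k_q / (k.k_ia * k.k_p * k.k_iq)
        + b * q * k.k_a / (k.k_ia * k.k_b * k.k_iq)
        + p * q / (k.k_p * k.k_iq)
        + p * b * a / (k.k_ia * k.k_b * k.k_ip)
        + b * p * q / (k.k_ib * k.k_p * k.k_iq)
    )
    return num / den


def haldane_diagnostic(k: KineticConstants) -> dict[str, float]:
    """Report (never enforce) the Haldane-relation consistency of a
    reversible constant set.

    The ordered bi-bi Haldane relation gives the equilibrium constant implied
    by the kinetic constants as ``Keq = kcat_f*K_p*K_iq / (kcat_r*K_ia*K_b)``
    (dimensionless, H+ omitted).  The tabulated equilibrium value is printed
    on a "×1e-12 M" scale whose reading is ambiguous, so the ratio
    implied/tabulated is reported under both readings rather than guessed:
    ``ratio_molar`` treats the printed number as ``value × 1e-12 M`` and
    ``ratio_printed`` compares against the bare printed number.
    """
    if not k.reversible:
        raise ValueError(f"{k.enzyme_id} is irreversible; no Haldane relation applies")
    implied = (k.kcat_f * k.k_p * k.k_iq) / (k.kcat_r * k.k_ia * k.k_b)
    out = {"implied_keq": implied}
    if k.k_eq is not None:
        out["ratio_printed"] = implied / k.k_eq
        out["ratio_molar"] = implied / (k.k_eq * 1e-12)
    return out
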