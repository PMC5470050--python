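"""Independent exact-arithmetic re-implementation of the three rate laws.

Transcribed directly from the published rational expressions using the
original K11..K38 / V11..V32 symbols and evaluated in `fractions.Fraction`
arithmetic, so it shares no code (and no floating-point rounding) with the
package implementation it checks.
"""

from fractions import Fraction as F

# Table constants, exact
K11, K12, K13, K14 = F(180), F(17000), F(800), F(100)
K15, K16, K17, K18 = F(270), F(90000), F(1100), F(31)
K21, K22, K25, K28 = F(20), F(9), F(70), F(100)
K31, K32, K33, K34 = F(24), F(120), F(6000), F(100)
K35, K36, K37, K38 = F(8), F(130), F(130000), F(100)
V11, V12 = F(40), F(340)
V21 = F(1)
V31, V32 = F(550), F(60)


def _f(x):
    return F(x) if not isinstance(x, float) else F.from_float(x)


def adh_rate(x1, x2, x4, nadh, vmax_f, vmax_r):
    """V_ADH: X[1]=NAD+, X[2]=ethanol, X[4]=acetaldehyde."""
    x1, x2, x4, nadh, vf, vr = map(_f, (x1, x2, x4, nadh, vmax_f, vmax_r))
    num = vf * x1 * x2 / K15 / K12 - vr * x4 * nadh / K13 / K18
    den = (
        1 + x1 / K15 + x2 * K11 / K15 / K12 + x4 * K14 / K18 / K13 + nadh / K18
        + x1 * x2 / K15 / K12 + x1 * x4 * K14 / K15 / K13 / K18
        + x2 * nadh * K11 / K15 / K12 / K18 + x4 * nadh / K13 / K18
        + x1 * x2 * x4 / K15 / K12 / K17 + x2 * x4 * nadh / K16 / K13 / K18
    )
    return num / den


def ald_rate(x1, x4, nadh, vmax_f):
    x1, x4, nadh, vf = map(_f, (x1, x4, nadh, vmax_f))
    num = vf * x1 * x4
    den = x1 * x4 + x1 * K22 + (x4 * K21 + K25 * K22) * (1 + nadh / K28)
    if den == 0:
        return F(0)
    return num / den


def ldh_rate(x1, x3, nadh, lact, vmax_f, vmax_r):
    """V_LDH: X[1]=NAD+, X[3]=pyruvate."""
    x1, x3, nadh, lact, vf, vr = map(_f, (x1, x3, nadh, lact, vmax_f, vmax_r))
    num = vf * nadh * x3 / K35 / K32 - vr * lact * x1 / K33 / K38
    den = (
        1 + nadh / K35 + x3 * K31 / K35 / K32 + nadh * K34 / K38 / K33 + x1 / K38
        + nadh * x3 / K35 / K32 + nadh * lact * K34 / K35 / K33 / K38
        + x3 * x1 * K31 / K35 / K32 / K38 + lact * x1 / K33 / K38
        + lact * x3 * nadh / K35 / K32 / K37 + x3 * lact * x1 / K36 / K33 / K38
    )
    return num / den
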