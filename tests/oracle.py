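"""Arbitrary-precision transcription of the two-level unified model.

Independent of the package's vectorised evaluator: a direct term-by-term
mpmath rendering of the model used as the high-precision reference in
tests. Kept deliberately naive.
"""

from mpmath import erf, exp, mp, mpf, sqrt

mp.dps = 40


def unified_intensity_mp(params: dict, q) -> float:
    """I(q) at one q value, computed at 40 decimal digits."""
    q = mpf(repr(float(q)))
    rg = {1: mpf(repr(float(params["rg1"]))),
          2: mpf(repr(float(params["rg2"]))),
          3: mpf(0)}
    total = mpf(repr(float(params["background"])))
    for i in (1, 2):
        g = mpf(repr(float(params[f"g{i}"])))
        b = mpf(repr(float(params[f"b{i}"])))
        p = mpf(repr(float(params[f"p{i}"])))
        q_star = q * erf(q * rg[i] / sqrt(6)) ** -3
        total += g * exp(-(q ** 2) * rg[i] ** 2 / 3)
        total += b * exp(-(q ** 2) * rg[i + 1] ** 2 / 3) * (1 / q_star) ** p
    return float(total)
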