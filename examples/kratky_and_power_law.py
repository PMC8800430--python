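"""Kratky transform and local power-law slope of a SAXS curve.

The Kratky plot q^2 I(q) turns each Guinier level into a peak: the
published ground/middle parameters produce the reported bump near
q = 0.9 nm^-1. The log-log slope over 0.07-0.5 nm^-1 sits near 2.3,
the signature of platelet-shaped scatterers (a thin plate gives
I ~ q^-2).
"""

import numpy as np

import cellugel as cg
from cellugel.tables import unified_params_published

def interior_kratky_peak(curve):
    """q of a local maximum of q^2 I(q) away from the window edges, if any."""
    k = cg.kratky_transform(curve)
    y = k.intensity
    local_max = (y[1:-1] > y[:-2]) & (y[1:-1] > y[2:])
    qs = k.q[1:-1][local_max]
    return float(qs[0]) if qs.size else None


params = unified_params_published("ground", "middle")
curve = cg.generate_saxs_curve(cg.SynthConfig(
    kind="saxs", noise=0.0, grid={"n": 600}, truth=params.to_dict()))

q_peak = interior_kratky_peak(curve)
print(f"ground/middle Kratky peak at q = {q_peak:.2f} nm^-1 "
      f"(the reported clear peak sits near 0.90 nm^-1)")

space_curve = cg.generate_saxs_curve(cg.SynthConfig(
    kind="saxs", noise=0.0, grid={"n": 600},
    truth=unified_params_published("space", "middle").to_dict()))
print(f"space/middle interior Kratky peak: {interior_kratky_peak(space_curve)}")
print("the compact-particle peak appears only in the ground/middle profile,")
print("where sedimented material concentrated mid-capillary")

exponent, stderr = cg.local_power_law_slope(curve, 0.07, 0.5)
print(f"power-law exponent over 0.07-0.5 nm^-1: {exponent:.3f} +- {stderr:.3f}")
print("an exponent near 2 indicates thin platelet scatterers; the measured")
print("curves were reported to scale as Q^-2.28 .. Q^-2.35 in this window")

# positional residual: subtract the bottom-of-capillary curve
other = cg.generate_saxs_curve(cg.SynthConfig(
    kind="saxs", noise=0.0, grid={"n": 600},
    truth=unified_params_published("ground", "bottom").to_dict()))
residual = cg.subtract_reference(curve, other)
print(f"middle-minus-bottom residual at q=0.5 nm^-1: "
      f"{np.interp(0.5, residual.q, residual.intensity):+.3f} (a.u.)")
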