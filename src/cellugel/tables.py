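"""Published summary tables for the space-vs-ground cellulose II comparison.

The study's raw curves and micrographs are not deposited; its printed
summary tables are shipped here as small built-in fixtures so that the
positional averaging, parameter summaries and condition comparisons can be
recomputed and cross-checked. Values are transcribed verbatim (value,
reported uncertainty) per condition and capillary position.
"""

from __future__ import annotations

import pandas as pd

CONDITIONS = ("space", "ground")
POSITIONS = ("upper", "middle", "bottom")

# WAXS 020-reflection quantification: peak area (arbitrary units) and
# FWHM (degrees 2-theta) per condition and capillary position.
WAXS_020_TABLE = pd.DataFrame(
    [
        ("space", "upper", 125.0, 34.0, 0.379, 0.055),
        ("space", "middle", 88.8, 11.7, 0.282, 0.025),
        ("space", "bottom", 93.9, 13.9, 0.296, 0.029),
        ("ground", "upper", 188.0, 8.0, 0.250, 0.008),
        ("ground", "middle", 234.0, 14.0, 0.292, 0.011),
        ("ground", "bottom", 246.0, 20.0, 0.316, 0.015),
    ],
    columns=["condition", "position", "area", "area_err", "fwhm_deg", "fwhm_err"],
)

#: printed positional averages of the WAXS table (area truncated as printed)
WAXS_020_PRINTED_AVERAGES = {
    "space": {"area": 103.0, "fwhm_deg": 0.319},
    "ground": {"area": 222.0, "fwhm_deg": 0.286},
}

# Two-level unified-fit parameters per condition and position:
# (value, reported uncertainty). chi2 per point has no printed uncertainty.
_T2 = {
    ("space", "upper"): dict(
        chi2_per_point=0.0849, background=(0.791, 0.066), rg1=(34.4, 0.7),
        p1=(2.78, 0.032), b1=(0.619, 0.051), g1=(3360, 125),
        rg2=(6.48, 0.41), p2=(2.71, 0.16), b2=(1.32, 0.10), g2=(56.4, 9.1),
    ),
    ("space", "middle"): dict(
        chi2_per_point=0.0559, background=(0.746, 0.065), rg1=(35.5, 0.7),
        p1=(2.75, 0.03), b1=(0.67, 0.05), g1=(3670, 151),
        rg2=(6.56, 0.41), p2=(2.72, 0.15), b2=(1.34, 0.10), g2=(58.8, 9.3),
    ),
    ("space", "bottom"): dict(
        chi2_per_point=0.0525, background=(0.735, 0.066), rg1=(34.4, 0.8),
        p1=(2.80, 0.04), b1=(0.526, 0.056), g1=(2980, 134),
        rg2=(6.78, 0.45), p2=(2.61, 0.14), b2=(1.27, 0.10), g2=(58.2, 9.9),
    ),
    ("ground", "upper"): dict(
        chi2_per_point=0.0492, background=(0.681, 0.068), rg1=(33.5, 0.5),
        p1=(2.76, 0.03), b1=(0.721, 0.058), g1=(3500, 100),
        rg2=(6.22, 0.44), p2=(2.81, 0.18), b2=(1.42, 0.10), g2=(55.9, 9.8),
    ),
    ("ground", "middle"): dict(
        chi2_per_point=0.195, background=(0.763, 0.070), rg1=(32.7, 0.2),
        p1=(2.66, 0.01), b1=(1.23, 0.02), g1=(4700, 53),
        rg2=(3.50, 0.00), p2=(5.80, 0.64), b2=(4.18, 0.32), g2=(20.7, 0.3),
    ),
    ("ground", "bottom"): dict(
        chi2_per_point=0.140, background=(0.688, 0.062), rg1=(32.4, 0.2),
        p1=(2.68, 0.01), b1=(0.943, 0.021), g1=(3500, 55),
        rg2=(4.00, 0.00), p2=(6.39, 0.73), b2=(1.94, 0.09), g2=(23.9, 0.4),
    ),
}


def unified_fit_table() -> pd.DataFrame:
    """Published unified-fit parameters as a tidy frame (one row per fit)."""
    rows = []
    for (cond, pos), params in _T2.items():
        row = {"condition": cond, "position": pos, "chi2_per_point": params["chi2_per_point"]}
        for key, val in params.items():
            if key == "chi2_per_point":
                continue
            row[key], row[key + "_err"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def unified_params_published(condition: str, position: str):
    """Published unified-model parameters as a UnifiedModelParams instance."""
    from .saxs import UnifiedModelParams

    p = _T2[(condition, position)]
    return UnifiedModelParams(
        background=p["background"][0],
        g1=p["g1"][0], b1=p["b1"][0], rg1=p["rg1"][0], p1=p["p1"][0],
        g2=p["g2"][0], b2=p["b2"][0], rg2=p["rg2"][0], p2=p["p2"][0],
    )


# Ribbon-diameter statistics from SEM image analysis (µm where dimensional).
DIAMETER_TABLE = pd.DataFrame(
    {
        "space": dict(
            mean=0.254, sd=0.128, mode=0.197, median=0.295,
            min=0.0491, max=1.38, skewness=1.31, kurtosis=2.70, n=76869,
        ),
        "ground": dict(
            mean=0.584, sd=0.370, mode=0.442, median=0.639,
            min=0.0491, max=3.49, skewness=1.65, kurtosis=3.91, n=30190,
        ),
    }
)

#: mean molecular weight (Da) and derived mean DP as printed
MALDI_PRINTED = {"space": {"mean_mw": 1160.0, "mean_dp": 6.89},
                 "ground": {"mean_mw": 1072.0, "mean_dp": 6.35}}

#: cellulose II reference lattice spacings (Å) for reflection assignment
CELLULOSE_II_D_SPACINGS = {"1-10": 7.23, "110": 4.45, "020": 4.03}

#: the corresponding peak positions reported in Q (nm^-1)
CELLULOSE_II_Q_PEAKS = {"1-10": 8.69, "110": 14.1, "020": 15.6}
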