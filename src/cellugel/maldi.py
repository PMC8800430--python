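"""Cellodextrin series identification and DP estimation from MALDI-ToF spectra.

Linear beta-1,4-glucans ionise as a comb of peaks spaced by one
anhydroglucose residue (162.14 Da average mass); each peak sits at
``m_n = unit_mass * n + adduct_mass`` for degree of polymerization n.
The peak tops across the series follow a roughly Gaussian envelope whose
centre is the mean molecular weight; the mean DP follows from the adduct
relation ``DP = (MW - adduct_mass) / unit_mass``.

The default adduct mass of 41.0 Da corresponds to the condensation water
plus a sodium cation ([M + Na]+ of the free oligosaccharide), the usual
MALDI species for underivatised oligosaccharides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy import optimize, signal

#: average anhydroglucose residue mass (Da)
UNIT_MASS = 162.14
#: default adduct mass: H2O (18.0) + Na (23.0)
ADDUCT_MASS = 41.0

from .curves import MassSpectrum


@dataclass
class DPSeries:
    """A consecutive run of cellodextrin peaks indexed by DP."""

    entries: List[Tuple[int, float, float]]  # (n, mz_obs, height)
    adduct_mass: float = ADDUCT_MASS
    unit_mass: float = UNIT_MASS
    reliable: bool = True

    def __post_init__(self):
        ns = [n for n, _, _ in self.entries]
        if ns and any(b - a != 1 for a, b in zip(ns, ns[1:])):
            raise ValueError("series DP indices must be consecutive")

    @property
    def n_values(self) -> np.ndarray:
        return np.array([n for n, _, _ in self.entries], dtype=int)

    @property
    def mz_values(self) -> np.ndarray:
        return np.array([m for _, m, _ in self.entries])

    @property
    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h in self.entries])

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class DPSummary:
    """Gaussian-envelope summary: mean MW (Da), mean DP, observed DP range."""

    mean_mw: float
    mean_dp: float
    dp_min: int
    dp_max: int
    envelope_sigma: float  # Da
    envelope_amplitude: float = float("nan")


def mw_to_dp(mw: float, adduct_mass: float = ADDUCT_MASS,
             unit_mass: float = UNIT_MASS) -> float:
    """Degree of polymerization (MW - adduct) / residue mass."""
    if mw <= adduct_mass:
        raise ValueError("molecular weight must exceed the adduct mass")
    return (mw - adduct_mass) / unit_mass


def dp_to_mw(dp: float, adduct_mass: float = ADDUCT_MASS,
             unit_mass: float = UNIT_MASS) -> float:
    """Inverse of :func:`mw_to_dp`."""
    return dp * unit_mass + adduct_mass


def noise_floor(intensity: np.ndarray) -> float:
    """Robust peak-acceptance floor: median + 5 * MAD of the spectrum."""
    med = float(np.median(intensity))
    mad = float(np.median(np.abs(intensity - med)))
    return med + 5.0 * mad


def pick_series_peaks(
    spectrum: MassSpectrum,
    adduct_mass: float = ADDUCT_MASS,
    unit_mass: float = UNIT_MASS,
    match_tol: float = 2.0,
) -> DPSeries:
    """Match local maxima to the cellodextrin mass comb.

    Local maxima above ``median + 5 MAD`` are matched to the grid
    ``unit_mass * n + adduct_mass`` within ``match_tol`` Da; the returned
    series is the longest consecutive run of matched n (highest peak wins
    when several maxima match the same n). Fewer than 3 consecutive
    matches flags the series unreliable; no qualifying maxima gives an
    empty (unreliable) series.
    """
    if not (0 < match_tol < unit_mass / 4):
        raise ValueError("match_tol must lie in (0, unit_mass/4)")
    floor = noise_floor(spectrum.intensity)
    idx, _ = signal.find_peaks(spectrum.intensity, height=floor)
    matched = {}
    for i in idx:
        mz = spectrum.mz[i]
        n = round((mz - adduct_mass) / unit_mass)
        if n < 1:
            continue
        if abs(mz - (unit_mass * n + adduct_mass)) <= match_tol:
            h = spectrum.intensity[i]
            if n not in matched or h > matched[n][1]:
                matched[n] = (mz, h)
    if not matched:
        return DPSeries([], adduct_mass, unit_mass, reliable=False)
    # longest consecutive run of matched n
    ns = sorted(matched)
    best_run, run = [], [ns[0]]
    for a, b in zip(ns, ns[1:]):
        if b == a + 1:
            run.append(b)
        else:
            if len(run) > len(best_run):
                best_run = run
            run = [b]
    if len(run) > len(best_run):
        best_run = run
    entries = [(n, float(matched[n][0]), float(matched[n][1])) for n in best_run]
    return DPSeries(entries, adduct_mass, unit_mass, reliable=len(entries) >= 3)


def fit_gaussian_envelope(series: DPSeries) -> DPSummary:
    """Gaussian fit through the series peak tops in m/z space.

    The fitted centre is the mean molecular weight; mean DP follows from
    the adduct relation. Requires at least 4 series entries.
    """
    if len(series) < 4:
        raise ValueError("need at least 4 series peaks for an envelope fit")
    mz, h = series.mz_values, series.heights
    if np.any(h <= 0):
        raise ValueError("peak heights must be positive")

    def gauss(x, amp, mu, sigma):
        return amp * np.exp(-((x - mu) ** 2) / (2.0 * sigma ** 2))

    # degenerate flat envelope: the centre is the series midpoint by symmetry
    if np.ptp(h) <= 1e-9 * h.max():
        mu = 0.5 * float(mz.min() + mz.max())
        return DPSummary(
            mean_mw=mu,
            mean_dp=mw_to_dp(mu, series.adduct_mass, series.unit_mass),
            dp_min=int(series.n_values.min()),
            dp_max=int(series.n_values.max()),
            envelope_sigma=float("inf"),
            envelope_amplitude=float(h.mean()),
        )

    # moment-based start
    w = h / h.sum()
    mu0 = float(np.sum(w * mz))
    sig0 = float(np.sqrt(np.sum(w * (mz - mu0) ** 2))) or series.unit_mass
    try:
        popt, _ = optimize.curve_fit(
            gauss, mz, h, p0=(h.max(), mu0, sig0),
            bounds=([0, mz.min() - 5 * series.unit_mass, 1e-3],
                    [np.inf, mz.max() + 5 * series.unit_mass, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"envelope fit did not converge: {exc}") from exc
    amp, mu, sigma = map(float, popt)
    return DPSummary(
        mean_mw=mu,
        mean_dp=mw_to_dp(mu, series.adduct_mass, series.unit_mass),
        dp_min=int(series.n_values.min()),
        dp_max=int(series.n_values.max()),
        envelope_sigma=sigma,
        envelope_amplitude=amp,
    )
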