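"""WAXS crystalline-peak quantification over a smooth solvent background.

The aqueous samples scatter as a smooth, monotonically increasing water
background over 5-16 nm^-1 on which the cellulose II reflections sit.
The background is estimated from points outside declared peak windows with
a monotonicity-constrained low-order polynomial; each peak is then fitted
as a Gaussian on the background-subtracted profile. Positions convert to
lattice spacings through d = 2 pi / Q and to scattering angles through
Q = 4 pi sin(theta) / lambda.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from .curves import ScatteringCurve
from .tables import CELLULOSE_II_D_SPACINGS

#: area of a Gaussian = amplitude * FWHM * sqrt(pi / (4 ln 2))
GAUSS_AREA_FACTOR = math.sqrt(math.pi / (4.0 * math.log(2.0)))
_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: default peak windows: +- 0.8 nm^-1 around the cellulose II positions
DEFAULT_PEAK_WINDOWS = ((7.89, 9.49), (13.3, 14.9), (14.8, 16.4))


@dataclass
class InstrumentGeometry:
    """Beamline geometry; only the wavelength enters any computation."""

    wavelength: float = 0.92  # Angstrom
    camera_length_mm: Optional[float] = None  # metadata only

    def __post_init__(self):
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")


@dataclass
class PeakFit:
    """A deconvolved Gaussian diffraction peak."""

    center_q: float          # nm^-1
    fwhm_q: float            # nm^-1
    area: float              # intensity * nm^-1
    center_q_err: float = float("nan")
    fwhm_q_err: float = float("nan")
    area_err: float = float("nan")
    center_2theta: float = float("nan")  # degrees, filled by geometry conversion
    fwhm_2theta: float = float("nan")
    window: Tuple[float, float] = (0.0, 0.0)
    absent: bool = False

    def with_angles(self, geometry: InstrumentGeometry) -> "PeakFit":
        out = PeakFit(**self.__dict__)
        out.center_2theta = q_to_two_theta(self.center_q, geometry)
        out.fwhm_2theta = fwhm_q_to_fwhm_two_theta(self.center_q, self.fwhm_q, geometry)
        return out


@dataclass
class ReflectionAssignment:
    """A peak labelled with its cellulose II Miller plane via d = 2 pi / Q."""

    peak: PeakFit
    d_obs: float             # Angstrom
    plane_label: str         # "1-10", "110", "020" or "unassigned"
    d_ref: Optional[float]


# ---------------------------------------------------------------------------
# conversions


def q_to_d(q: float) -> float:
    """Lattice spacing d = 2 pi / Q, with Q in nm^-1 and d in Angstrom."""
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q must be positive")
    d = 2.0 * np.pi / q * 10.0
    return float(d) if d.ndim == 0 else d


def d_to_q(d: float) -> float:
    """Inverse of :func:`q_to_d` (d in Angstrom -> Q in nm^-1)."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("d must be positive")
    q = 2.0 * np.pi / (d / 10.0)
    return float(q) if q.ndim == 0 else q


def q_to_two_theta(q, geometry: InstrumentGeometry) -> float:
    """Scattering angle 2 theta (degrees) from Q = 4 pi sin(theta)/lambda.

    Q in nm^-1, wavelength in Angstrom.
    """
    q = np.asarray(q, dtype=float)
    arg = q * (geometry.wavelength / 10.0) / (4.0 * np.pi)
    if np.any(arg > 1.0):
        raise ValueError("q lambda / 4 pi exceeds 1: unphysical angle")
    tt = np.degrees(2.0 * np.arcsin(arg))
    return float(tt) if tt.ndim == 0 else tt


def fwhm_q_to_fwhm_two_theta(center_q: float, fwhm_q: float,
                             geometry: InstrumentGeometry) -> float:
    """FWHM in degrees 2 theta via conversion of the half-maximum endpoints."""
    lo = q_to_two_theta(center_q - fwhm_q / 2.0, geometry)
    hi = q_to_two_theta(center_q + fwhm_q / 2.0, geometry)
    return hi - lo


# ---------------------------------------------------------------------------
# background and peaks


def estimate_smooth_background(
    profile: ScatteringCurve,
    peak_windows: Sequence[Tuple[float, float]] = DEFAULT_PEAK_WINDOWS,
    degree: int = 4,
    monotone: bool = True,
) -> ScatteringCurve:
    """Smooth monotone background from points outside the peak windows.

    A polynomial of degree <= 4 is least-squares fitted to the out-of-window
    points; when ``monotone`` (the default, reflecting the smooth water
    scattering assumption) its derivative is constrained to be single-signed
    over the q range, matching the sign of the out-of-window trend.
    """
    if degree > 4:
        raise ValueError("background degree is limited to 4")
    q, y = profile.q, profile.intensity
    outside = np.ones(q.size, dtype=bool)
    for lo, hi in peak_windows:
        if hi < q.min() or lo > q.max():
            raise ValueError(f"window ({lo}, {hi}) outside the profile q range")
        outside &= ~((q >= lo) & (q <= hi))
    if outside.sum() < 0.3 * q.size:
        raise ValueError("fewer than 30% of points lie outside the peak windows")

    # scale q to [-1, 1] for conditioning
    qmid, qhalf = (q.max() + q.min()) / 2.0, (q.max() - q.min()) / 2.0
    x = (q - qmid) / qhalf
    xo, yo = x[outside], y[outside]
    V = np.vander(xo, degree + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(V, yo, rcond=None)

    def poly(c, xx):
        return np.vander(xx, degree + 1, increasing=True) @ c

    def dpoly(c, xx):
        dv = np.vander(xx, degree + 1, increasing=True)[:, :-1] * np.arange(1, degree + 1)
        return dv @ c[1:]

    if monotone:
        trend = 1.0 if yo[-1] >= yo[0] else -1.0
        deriv = dpoly(coef, x)
        if np.any(trend * deriv < 0):
            # refit with derivative-sign constraints on the full grid
            res = optimize.minimize(
                lambda c: np.sum((poly(c, xo) - yo) ** 2),
                coef,
                constraints=[{"type": "ineq", "fun": lambda c: trend * dpoly(c, x)}],
                method="SLSQP",
                options={"maxiter": 500},
            )
            coef = res.x

    bg = poly(coef, x)
    out = profile.with_intensity(bg, None)
    out.meta = dict(profile.meta, background_coef=list(coef))
    return out


def _gaussian(x, amp, center, sigma):
    return amp * np.exp(-((x - center) ** 2) / (2.0 * sigma ** 2))


def fit_peaks(
    profile: ScatteringCurve,
    background: ScatteringCurve,
    windows: Sequence[Tuple[float, float]] = DEFAULT_PEAK_WINDOWS,
) -> list:
    """Fit one Gaussian per window to the background-subtracted profile.

    Area = amplitude * FWHM * sqrt(pi / (4 ln 2)). A window whose fitted
    amplitude is non-positive is reported with area 0 and ``absent=True``.
    """
    if not np.array_equal(profile.q, background.q):
        raise ValueError("background must share the profile's q grid")
    q = profile.q
    excess = profile.intensity - background.intensity
    peaks = []
    for lo, hi in windows:
        mask = (q >= lo) & (q <= hi)
        if mask.sum() < 5:
            raise ValueError(f"window ({lo}, {hi}) holds fewer than 5 points")
        qx, yx = q[mask], excess[mask]
        amp0 = float(yx.max())
        c0 = float(qx[np.argmax(yx)])
        s0 = (hi - lo) / 6.0
        if amp0 <= 0:
            peaks.append(PeakFit(center_q=c0, fwhm_q=float("nan"), area=0.0,
                                 window=(lo, hi), absent=True))
            continue
        try:
            popt, pcov = optimize.curve_fit(
                _gaussian, qx, yx, p0=(amp0, c0, s0),
                bounds=([0.0, lo, 1e-4], [np.inf, hi, (hi - lo)]),
                maxfev=20000,
            )
        except RuntimeError:
            peaks.append(PeakFit(center_q=c0, fwhm_q=float("nan"), area=0.0,
                                 window=(lo, hi), absent=True))
            continue
        amp, center, sigma = popt
        # amplitude at numerical-noise level relative to the window: no peak
        if amp <= 1e-9 * float(np.max(np.abs(profile.intensity[mask]))):
            peaks.append(PeakFit(center_q=float(center), fwhm_q=float("nan"),
                                 area=0.0, window=(lo, hi), absent=True))
            continue
        perr = np.sqrt(np.diag(pcov))
        fwhm = sigma / _FWHM_TO_SIGMA
        fwhm_err = perr[2] / _FWHM_TO_SIGMA
        area = amp * fwhm * GAUSS_AREA_FACTOR
        # first-order error propagation for the area product
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.sqrt((perr[0] / amp) ** 2 + (fwhm_err / fwhm) ** 2)
        if amp <= 0:
            peaks.append(PeakFit(center_q=float(center), fwhm_q=float(fwhm),
                                 area=0.0, window=(lo, hi), absent=True))
            continue
        peaks.append(PeakFit(
            center_q=float(center), fwhm_q=float(fwhm), area=float(area),
            center_q_err=float(perr[1]), fwhm_q_err=float(fwhm_err),
            area_err=float(area * rel), window=(lo, hi),
        ))
    return peaks


def assign_reflections(
    peaks: Sequence[PeakFit],
    reference: Optional[dict] = None,
    tolerance: float = 0.02,
) -> list:
    """Label peaks with the nearest reference plane within tolerance.

    One-to-one: each plane is claimed by the closest peak; relative-d ties
    break toward the lower reference spacing. Peaks with no plane within
    ``tolerance`` (fractional) are labelled ``"unassigned"``.
    """
    if not (0 < tolerance <= 0.1):
        raise ValueError("tolerance must lie in (0, 0.1]")
    if reference is None:
        reference = CELLULOSE_II_D_SPACINGS
    # candidate (relative distance, -d_ref for tie-break) per peak/plane
    assignments = []
    claimed = set()
    order = []
    for idx, peak in enumerate(peaks):
        d_obs = q_to_d(peak.center_q)
        for label, d_ref in reference.items():
            rel = abs(d_obs - d_ref) / d_ref
            if rel <= tolerance:
                order.append((rel, d_ref, idx, label))
    order.sort(key=lambda t: (t[0], t[1]))
    chosen = {}
    for rel, d_ref, idx, label in order:
        if idx in chosen or label in claimed:
            continue
        chosen[idx] = (label, d_ref)
        claimed.add(label)
    for idx, peak in enumerate(peaks):
        d_obs = q_to_d(peak.center_q)
        label, d_ref = chosen.get(idx, ("unassigned", None))
        assignments.append(ReflectionAssignment(peak=peak, d_obs=d_obs,
                                                plane_label=label, d_ref=d_ref))
    return assignments


def summarize_positions(values_by_position: dict, ndigits: Optional[int] = None) -> float:
    """Arithmetic mean of a quantity over the three capillary positions.

    Requires exactly the upper/middle/bottom positions, mirroring the
    published per-capillary averages.
    """
    required = {"upper", "middle", "bottom"}
    if set(values_by_position) != required:
        missing = required - set(values_by_position)
        extra = set(values_by_position) - required
        raise ValueError(f"positions mismatch: missing {sorted(missing)}, extra {sorted(extra)}")
    mean = float(np.mean([values_by_position[k] for k in ("upper", "middle", "bottom")]))
    return round(mean, ndigits) if ndigits is not None else mean
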