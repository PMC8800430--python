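"""Seeded synthetic-data generators with machine-readable ground truth.

Every analysis stage in this package is validated against data whose truth
is known exactly: SAXS curves are forward evaluations of the two-level
unified model with multiplicative Gaussian noise (constant fractional
error, the count-dominated synchrotron regime at moderate intensity);
WAXS profiles are a smooth monotone water background plus Gaussian peaks
with additive noise; MALDI spectra are a cellodextrin mass comb under a
Gaussian DP envelope; ribbon images are straight constant-width segments
drawn from a stated width distribution.

All generators are deterministic in the seed and echo their ground truth
in the returned object's ``meta["truth"]`` block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


import numpy as np

from .curves import MassSpectrum, Micrograph, ScatteringCurve
from .maldi import ADDUCT_MASS, UNIT_MASS
from .saxs import UnifiedModelParams, unified_intensity

KINDS = ("saxs", "waxs", "maldi", "ribbon_image")


@dataclass
class SynthConfig:
    """One generator request: what to simulate, with what truth, at what noise.

    ``grid`` is the axis specification (q range / m/z range / image size
    and pixel size); ``truth`` is the generator-specific ground-truth
    block. ``noise`` is a single dimensionless fractional noise level;
    0 means the output equals the noiseless forward model exactly.
    """

    kind: str
    seed: int = 0
    noise: float = 0.0
    grid: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.noise < 0:
            raise ValueError("noise must be non-negative")


def _axis(grid: dict, lo_key, hi_key, n_key, lo, hi, n, spacing="log") -> np.ndarray:
    lo = grid.get(lo_key, lo)
    hi = grid.get(hi_key, hi)
    n = int(grid.get(n_key, n))
    if not (hi > lo > 0 if spacing == "log" else hi > lo):
        raise ValueError("grid bounds must be increasing (and positive for log)")
    if grid.get("spacing", spacing) == "log":
        return np.geomspace(lo, hi, n)
    return np.linspace(lo, hi, n)


# ---------------------------------------------------------------------------
# SAXS


def generate_saxs_curve(config: SynthConfig) -> ScatteringCurve:
    """Unified-model curve with multiplicative Gaussian noise.

    ``truth`` holds the unified-model parameter dict (or a
    ``UnifiedModelParams``); ``grid`` accepts qmin/qmax/n/spacing
    (default 0.07-2.5 nm^-1, 200 log-spaced points, the measured window).
    ``intensity = I_model * (1 + noise * eps)`` with standard-normal eps;
    ``sigma = noise * I_model``. If any point would turn negative, eps is
    deterministically truncated at +-5 and a warning flag is recorded.
    """
    if config.kind != "saxs":
        raise ValueError("config.kind must be 'saxs'")
    truth = config.truth
    params = truth if isinstance(truth, UnifiedModelParams) else UnifiedModelParams.from_dict(truth)
    q = _axis(config.grid, "qmin", "qmax", "n", 0.07, 2.5, 200, "log")
    model = unified_intensity(params, q)
    meta = {"truth": params.to_dict(), "seed": config.seed, "noise": config.noise}
    if config.noise == 0:
        return ScatteringCurve(q, model, None, meta=meta,
                               condition=config.grid.get("condition", ""))
    rng = np.random.default_rng(config.seed)
    eps = rng.standard_normal(q.size)
    if np.any(1.0 + config.noise * eps <= 0):
        eps = np.clip(eps, -5.0, 5.0)
        meta["truncated_noise"] = True
        if np.any(1.0 + config.noise * eps <= 0):
            raise ValueError("noise level too large: negative intensity even at 5 sigma")
    intensity = model * (1.0 + config.noise * eps)
    sigma = config.noise * model
    return ScatteringCurve(q, intensity, sigma, meta=meta,
                           condition=config.grid.get("condition", ""))


# ---------------------------------------------------------------------------
# WAXS

#: default smooth monotone water background over 5-16 nm^-1 (poly in q)
DEFAULT_WAXS_BACKGROUND = (20.0, 6.0, 0.2)


def waxs_background(q: np.ndarray, coef) -> np.ndarray:
    """Polynomial background sum_k coef[k] q^k; must be monotone on the grid."""
    bg = np.polynomial.polynomial.polyval(q, coef)
    d = np.diff(bg)
    if np.any(d < 0) and np.any(d > 0):
        raise ValueError("background specification is not monotone on the grid")
    return bg


def generate_waxs_profile(config: SynthConfig) -> ScatteringCurve:
    """Smooth background + Gaussian peaks + additive Gaussian noise.

    ``truth`` keys: ``peaks`` (list of [center_q, fwhm_q, area]) and
    optionally ``background`` (polynomial coefficients, default the water
    ramp). Additive noise SD = noise * median(clean profile). Peak pairs
    separated by less than 0.2 x their mean FWHM are still generated but
    flagged ``unresolvable``.
    """
    if config.kind != "waxs":
        raise ValueError("config.kind must be 'waxs'")
    q = _axis(config.grid, "qmin", "qmax", "n", 5.0, 16.0, 600, "linear")
    coef = tuple(config.truth.get("background", DEFAULT_WAXS_BACKGROUND))
    peaks = [tuple(map(float, p)) for p in config.truth.get("peaks", [])]
    profile = waxs_background(q, coef).copy()
    s2 = 8.0 * math.log(2.0)
    for center, fwhm, area in peaks:
        sigma = fwhm / math.sqrt(s2)
        amp = area / (sigma * math.sqrt(2.0 * math.pi))
        profile = profile + amp * np.exp(-((q - center) ** 2) / (2 * sigma * sigma))
    meta = {"truth": {"background": list(coef),
                      "peaks": [list(p) for p in peaks]},
            "seed": config.seed, "noise": config.noise}
    centers = sorted(peaks)
    for (c1, f1, _), (c2, f2, _) in zip(centers, centers[1:]):
        if c2 - c1 < 0.2 * 0.5 * (f1 + f2):
            meta["unresolvable"] = True
    if config.noise > 0:
        rng = np.random.default_rng(config.seed)
        profile = profile + config.noise * float(np.median(profile)) * rng.standard_normal(q.size)
    return ScatteringCurve(q, profile, None, meta=meta,
                           condition=config.grid.get("condition", ""))


# ---------------------------------------------------------------------------
# MALDI

#: default DP-envelope spread (DP units); keeps the discrete truncated
#: envelope's weighted mean within 0.01 of the configured centre on DP 4-11
DEFAULT_DP_SIGMA = 1.2


def generate_maldi_spectrum(config: SynthConfig) -> MassSpectrum:
    """Cellodextrin comb with a Gaussian DP envelope and baseline noise.

    ``truth`` keys: ``mean_dp`` (envelope centre), ``dp_sigma`` (spread in
    DP units, default 1.2), ``dp_min``/``dp_max`` (integer support,
    default 4-11), ``adduct_mass`` (default 41.0 Da), ``peak_sigma_mz``
    (rendered peak width, default 1.5 Da), ``amplitude`` (default 1000).
    Peaks sit exactly at ``162.14 n + adduct_mass``; baseline noise is
    zero-mean Gaussian with SD noise * amplitude, clipped at the zero
    detector floor.
    """
    if config.kind != "maldi":
        raise ValueError("config.kind must be 'maldi'")
    t = config.truth
    dp_min = int(t.get("dp_min", 4))
    dp_max = int(t.get("dp_max", 11))
    if dp_max < dp_min:
        raise ValueError("empty DP range")
    mean_dp = float(t.get("mean_dp", 6.9))
    dp_sigma = float(t.get("dp_sigma", DEFAULT_DP_SIGMA))
    if mean_dp <= 0 or dp_sigma <= 0:
        raise ValueError("mean DP and spread must be positive")
    adduct = float(t.get("adduct_mass", ADDUCT_MASS))
    unit = float(t.get("unit_mass", UNIT_MASS))
    peak_sigma = float(t.get("peak_sigma_mz", 1.5))
    amp = float(t.get("amplitude", 1000.0))

    mz = _axis(config.grid, "mz_min", "mz_max", "n", 500.0, 2000.0, 6000, "linear")
    n = np.arange(dp_min, dp_max + 1)
    centers = unit * n + adduct
    heights = amp * np.exp(-((n - mean_dp) ** 2) / (2 * dp_sigma ** 2))
    intensity = np.zeros_like(mz)
    for c, h in zip(centers, heights):
        intensity += h * np.exp(-((mz - c) ** 2) / (2 * peak_sigma ** 2))
    meta = {"truth": {"mean_dp": mean_dp, "dp_sigma": dp_sigma,
                      "dp_min": dp_min, "dp_max": dp_max,
                      "adduct_mass": adduct, "unit_mass": unit,
                      "peak_mz": centers.tolist(), "peak_heights": heights.tolist()},
            "seed": config.seed, "noise": config.noise}
    if config.noise > 0:
        rng = np.random.default_rng(config.seed)
        intensity = np.maximum(
            intensity + config.noise * amp * rng.standard_normal(mz.size), 0.0)
    return MassSpectrum(mz, intensity, meta=meta,
                        condition=config.grid.get("condition", ""))


# ---------------------------------------------------------------------------
# ribbon images


def render_ribbon(canvas: np.ndarray, center_rc, angle_deg: float,
                  length_px: float, width_px: float, value: float = 200.0) -> None:
    """Paint one straight constant-width ribbon onto ``canvas`` in place.

    A pixel belongs to the ribbon when its centre lies strictly within
    width/2 of the centreline segment (so an odd integer width centred on
    a pixel row spans exactly that many rows).
    """
    h, w = canvas.shape
    r0, c0 = center_rc
    th = math.radians(angle_deg)
    dr, dc = math.sin(th), math.cos(th)
    half_l, half_w = length_px / 2.0, width_px / 2.0
    pad = int(math.ceil(half_l + half_w)) + 1
    rmin = max(0, int(r0) - pad)
    rmax = min(h, int(r0) + pad + 1)
    cmin = max(0, int(c0) - pad)
    cmax = min(w, int(c0) + pad + 1)
    if rmin >= rmax or cmin >= cmax:
        return
    rr, cc = np.meshgrid(np.arange(rmin, rmax), np.arange(cmin, cmax), indexing="ij")
    pr, pc = rr - r0, cc - c0
    t = np.clip(pr * dr + pc * dc, -half_l, half_l)  # along-axis, clamped to ends
    dist2 = (pr - t * dr) ** 2 + (pc - t * dc) ** 2
    canvas[rmin:rmax, cmin:cmax][dist2 < half_w ** 2] = value


def generate_ribbon_image(config: SynthConfig) -> Micrograph:
    """Binary-contrast image of straight ribbons with known widths.

    ``grid``: ``shape`` (default (1024, 1024)) and ``pixel_size_um``
    (default 0.05). ``truth``: ``n_ribbons``; width distribution either
    ``width_um`` (fixed) or ``width_mean_um``/``width_sd_um`` (lognormal,
    defaults 0.254/0.128 µm); ``length_um`` range (default (5, 15));
    ``angle_deg`` range (default (0, 180)). ``noise`` > 0 applies a light
    Gaussian blur of that many pixels. Foreground 200, background 20.

    Errors if the requested width (fixed value or distribution mean) is
    below 3 px at the stated pixel size (unmeasurable); individual random
    draws below 3 px are rendered as drawn and recorded in the truth block.
    """
    if config.kind != "ribbon_image":
        raise ValueError("config.kind must be 'ribbon_image'")
    shape = tuple(config.grid.get("shape", (1024, 1024)))
    if min(shape) < 64:
        raise ValueError("image must be at least 64x64 px")
    pixel_size = float(config.grid.get("pixel_size_um", 0.05))
    if pixel_size <= 0:
        raise ValueError("pixel size must be positive")
    t = config.truth
    n_ribbons = int(t.get("n_ribbons", 200))
    length_um = t.get("length_um", (5.0, 15.0))
    angle_deg = t.get("angle_deg", (0.0, 180.0))

    rng = np.random.default_rng(config.seed)
    if "width_um" in t:
        widths = np.full(n_ribbons, float(t["width_um"]))
        requested_px = float(t["width_um"]) / pixel_size
    else:
        mean = float(t.get("width_mean_um", 0.254))
        sd = float(t.get("width_sd_um", 0.128))
        var_ratio = (sd / mean) ** 2
        sigma = math.sqrt(math.log1p(var_ratio))
        mu = math.log(mean) - sigma ** 2 / 2.0
        widths = rng.lognormal(mu, sigma, size=n_ribbons)
        requested_px = mean / pixel_size
    if requested_px < 3.0:
        raise ValueError(
            f"requested width {requested_px:.2f} px is below the 3 px measurable floor")

    canvas = np.full(shape, 20.0)
    ribbons = []
    for width in widths:
        r0 = rng.uniform(0, shape[0])
        c0 = rng.uniform(0, shape[1])
        ang = rng.uniform(*angle_deg)
        length = rng.uniform(*length_um) / pixel_size
        render_ribbon(canvas, (r0, c0), ang, length, width / pixel_size)
        ribbons.append({"center_rc": [r0, c0], "angle_deg": ang,
                        "length_px": length, "width_um": float(width)})
    if config.noise > 0:
        from scipy import ndimage
        canvas = ndimage.gaussian_filter(canvas, sigma=config.noise)
    meta = {"truth": {"widths_um": [r["width_um"] for r in ribbons],
                      "ribbons": ribbons},
            "seed": config.seed, "noise": config.noise}
    return Micrograph(np.clip(np.round(canvas), 0, 255).astype(np.uint8),
                      pixel_size, meta=meta,
                      condition=config.grid.get("condition", ""))
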