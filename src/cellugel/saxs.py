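"""Two-level unified (Beaucage) SAXS model: evaluation, fitting, transforms.

The unified model describes scattering from a hierarchy of structural
levels, each contributing a Guinier exponential (prefactor ``G_i``, radius
of gyration ``Rg_i``) and a power law (prefactor ``B_i``, exponent ``P_i``)
whose low-q divergence is cut off through an error-function-rescaled
scattering vector::

    I(q) = bkg + sum_i [ G_i exp(-q^2 Rg_i^2 / 3)
                         + B_i exp(-q^2 Rg_{i+1}^2 / 3) (1/q*_i)^{P_i} ]

    q*_i = q [erf(q Rg_i / sqrt(6))]^(-3)

Two levels are used here, ordered large-to-small (``Rg_1 > Rg_2``), with
the convention ``Rg_3 = 0`` so the level-2 power law has no high-q cutoff.
At q -> 0 every power-law term vanishes (q* ~ q^-2 -> infinity) and
I -> bkg + G_1 + G_2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import lmfit
import numpy as np
from scipy import special, stats

from .curves import ScatteringCurve

#: fixed convention: the i = 2 power-law term has no high-q Guinier cutoff
RG3 = 0.0


@dataclass
class UnifiedModelParams:
    """Parameter set of the two-level unified model.

    Units: ``rg1``/``rg2`` in nm; prefactors and background in the
    intensity's (arbitrary) units; ``p1``/``p2`` dimensionless in (0, 8].
    Levels are ordered large-to-small: ``rg1 > rg2 > RG3 = 0``.
    """

    background: float
    g1: float
    b1: float
    rg1: float
    p1: float
    g2: float
    b2: float
    rg2: float
    p2: float

    def __post_init__(self):
        if self.background < 0 or self.g1 < 0 or self.g2 < 0 or self.b1 < 0 or self.b2 < 0:
            raise ValueError("background and prefactors must be non-negative")
        if not (self.rg1 > self.rg2 > RG3):
            raise ValueError("levels must be ordered rg1 > rg2 > 0")
        for p in (self.p1, self.p2):
            if not (0 < p <= 8):
                raise ValueError("power-law exponents must lie in (0, 8]")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("background", "g1", "b1", "rg1", "p1", "g2", "b2", "rg2", "p2")}

    @classmethod
    def from_dict(cls, d: dict) -> "UnifiedModelParams":
        return cls(**{k: d[k] for k in
                      ("background", "g1", "b1", "rg1", "p1", "g2", "b2", "rg2", "p2")})


@dataclass
class UnifiedModelEvaluation:
    """Pointwise evaluation of the unified model with per-level terms."""

    q: np.ndarray
    q_star_1: np.ndarray
    q_star_2: np.ndarray
    level_terms: dict  # keys: guinier_1, power_1, guinier_2, power_2
    total: np.ndarray


def _power_law_term(q: np.ndarray, b: float, rg_next: float, rg_cut: float,
                    p: float) -> np.ndarray:
    """B exp(-q^2 rg_next^2/3) (1/q*)^P with q* = q erf(q rg_cut/sqrt6)^-3.

    Evaluated in log space so the q* ~ q^-2 low-q divergence of the
    rescaled vector cannot overflow before the exponent damps it.
    """
    if b == 0:
        return np.zeros_like(q)
    erf = special.erf(q * rg_cut / math.sqrt(6.0))
    # log q* = log q - 3 log erf; erf > 0 for q > 0, rg_cut > 0
    log_qstar = np.log(q) - 3.0 * np.log(erf)
    log_term = math.log(b) - q * q * rg_next * rg_next / 3.0 - p * log_qstar
    return np.exp(log_term)


def q_star(q: np.ndarray, rg: float) -> np.ndarray:
    """Error-function-rescaled scattering vector q[erf(q rg/sqrt6)]^-3."""
    erf = special.erf(np.asarray(q, float) * rg / math.sqrt(6.0))
    return q * erf ** -3.0


def evaluate_unified_model(params: UnifiedModelParams, q) -> UnifiedModelEvaluation:
    """Evaluate the two-level unified model on a positive q grid (nm^-1)."""
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q must be strictly positive")
    terms = {
        "guinier_1": params.g1 * np.exp(-q * q * params.rg1 ** 2 / 3.0),
        "power_1": _power_law_term(q, params.b1, params.rg2, params.rg1, params.p1),
        "guinier_2": params.g2 * np.exp(-q * q * params.rg2 ** 2 / 3.0),
        "power_2": _power_law_term(q, params.b2, RG3, params.rg2, params.p2),
    }
    total = params.background + sum(terms.values())
    return UnifiedModelEvaluation(
        q=q,
        q_star_1=q_star(q, params.rg1),
        q_star_2=q_star(q, params.rg2),
        level_terms=terms,
        total=total,
    )


def unified_intensity(params: UnifiedModelParams, q) -> np.ndarray:
    """Model intensity only (convenience wrapper)."""
    return evaluate_unified_model(params, q).total


# ---------------------------------------------------------------------------
# fitting

_PARAM_NAMES = ("background", "g1", "b1", "rg1", "p1", "g2", "b2", "rg2", "p2")

#: generous default bounds; rg1 > rg2 ordering is enforced separately
DEFAULT_BOUNDS = {
    "background": (0.0, np.inf),
    "g1": (0.0, np.inf),
    "b1": (0.0, np.inf),
    "rg1": (1e-3, 1e4),
    "p1": (0.1, 8.0),
    "g2": (0.0, np.inf),
    "b2": (0.0, np.inf),
    "rg2": (1e-3, 1e4),
    "p2": (0.1, 8.0),
}


@dataclass
class UnifiedFitResult:
    """Fitted unified-model parameters with uncertainties and diagnostics."""

    params: UnifiedModelParams
    stderr: dict
    chi2_per_point: float
    residuals: np.ndarray
    converged: bool
    n_restarts: int = 0
    report: str = ""


def _make_lmfit_params(init: UnifiedModelParams, bounds: dict) -> lmfit.Parameters:
    pars = lmfit.Parameters()
    for name in _PARAM_NAMES:
        if name == "rg1":
            continue
        lo, hi = bounds[name]
        pars.add(name, value=float(np.clip(getattr(init, name), lo, hi)),
                 min=lo, max=hi)
    # ordering rg1 > rg2 via a strictly positive gap parameter
    lo1, hi1 = bounds["rg1"]
    gap0 = max(init.rg1 - init.rg2, 1e-3)
    pars.add("rg_gap", value=gap0, min=1e-6, max=hi1)
    pars.add("rg1", expr="rg2 + rg_gap", min=lo1, max=hi1)
    return pars


def _params_from_lmfit(pars) -> UnifiedModelParams:
    vals = {name: float(pars[name].value) for name in _PARAM_NAMES}
    return UnifiedModelParams(**vals)


def fit_unified_model(
    curve: ScatteringCurve,
    init: UnifiedModelParams,
    bounds: Optional[dict] = None,
    weighting: str = "auto",
    max_restarts: int = 5,
    restart_seed: int = 0,
) -> UnifiedFitResult:
    """Least-squares fit of the two-level unified model to a curve.

    Parameters
    ----------
    curve : ScatteringCurve
        At least 50 points spanning at least one decade in q.
    init : UnifiedModelParams
        Starting point (must satisfy the ordering invariant).
    bounds : dict, optional
        ``{name: (lo, hi)}`` overriding :data:`DEFAULT_BOUNDS` entries.
    weighting : {"auto", "sigma", "none"}
        ``sigma``: minimise (I_obs - I_model)/sigma. ``none``: minimise
        log I_obs - log I_model (unweighted log-intensity). ``auto`` picks
        ``sigma`` when uncertainties are present.
    max_restarts : int
        Seeded multi-start retries on non-convergence; best chi2 wins.

    Uses a bounded trust-region-reflective least-squares minimiser;
    parameter uncertainties are 1-sigma values from the covariance at the
    optimum.
    """
    q, i_obs = curve.q, curve.intensity
    if q.size < 50:
        raise ValueError("need at least 50 points to fit 9 parameters")
    if q.max() / q.min() < 10.0:
        raise ValueError("q range must span at least one decade")
    if not np.all(np.isfinite(i_obs)):
        raise ValueError("non-finite intensities")

    if weighting == "auto":
        weighting = "sigma" if curve.sigma is not None else "none"
    if weighting == "sigma" and curve.sigma is None:
        raise ValueError("sigma weighting requested but curve has no sigma")
    if weighting not in ("sigma", "none"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if weighting == "none" and np.any(i_obs <= 0):
        raise ValueError("log-intensity weighting needs positive intensities")

    eff_bounds = dict(DEFAULT_BOUNDS)
    if bounds:
        eff_bounds.update(bounds)

    def residual(pars):
        model = unified_intensity(_params_from_lmfit(pars), q)
        if weighting == "sigma":
            return (i_obs - model) / curve.sigma
        return np.log(i_obs) - np.log(np.maximum(model, 1e-300))

    rng = np.random.default_rng(restart_seed)
    best = None
    attempts = 0
    start = init
    while attempts <= max_restarts:
        pars = _make_lmfit_params(start, eff_bounds)
        minres = lmfit.minimize(residual, pars, method="least_squares")
        chi2pp = float(np.sum(minres.residual ** 2) / q.size)
        cand = (minres, chi2pp)
        if best is None or chi2pp < best[1]:
            best = cand
        if minres.success:
            break
        attempts += 1
        # perturb the initial guess deterministically and retry
        jitter = {k: v * rng.uniform(0.8, 1.2) if k not in ("p1", "p2")
                  else float(np.clip(v + rng.uniform(-0.3, 0.3), 0.2, 8.0))
                  for k, v in init.to_dict().items()}
        jitter["rg1"] = max(jitter["rg1"], jitter["rg2"] * 1.1)
        start = UnifiedModelParams(**jitter)

    minres, chi2pp = best
    fitted = _params_from_lmfit(minres.params)
    stderr = {}
    for name in _PARAM_NAMES:
        par = minres.params[name]
        stderr[name] = float(par.stderr) if par.stderr is not None else float("nan")
    return UnifiedFitResult(
        params=fitted,
        stderr=stderr,
        chi2_per_point=chi2pp,
        residuals=np.asarray(minres.residual),
        converged=bool(minres.success),
        n_restarts=attempts,
        report=lmfit.fit_report(minres),
    )


# ---------------------------------------------------------------------------
# transforms and summaries


def kratky_transform(curve: ScatteringCurve) -> ScatteringCurve:
    """Kratky transform: intensity -> q^2 I(q), sigma -> q^2 sigma."""
    q2 = curve.q ** 2
    sigma = q2 * curve.sigma if curve.sigma is not None else None
    return curve.with_intensity(q2 * curve.intensity, sigma)


def subtract_reference(curve: ScatteringCurve, reference: ScatteringCurve) -> ScatteringCurve:
    """Pointwise curve - reference on identical q grids (no interpolation).

    Sigmas, when both present, combine in quadrature.
    """
    if curve.q.size != reference.q.size or not np.array_equal(curve.q, reference.q):
        raise ValueError("q grids differ; subtraction requires identical grids")
    sigma = None
    if curve.sigma is not None and reference.sigma is not None:
        sigma = np.hypot(curve.sigma, reference.sigma)
    return curve.with_intensity(curve.intensity - reference.intensity, sigma)


def local_power_law_slope(curve: ScatteringCurve, qmin: float, qmax: float):
    """Power-law exponent p (I ~ q^-p) over [qmin, qmax] by log-log regression.

    Returns ``(exponent, stderr)`` where exponent is the negated slope of
    the least-squares line of log I vs log q.
    """
    mask = (curve.q >= qmin) & (curve.q <= qmax)
    if mask.sum() < 10:
        raise ValueError("need at least 10 points inside the window")
    if np.any(curve.intensity[mask] <= 0):
        raise ValueError("intensities must be positive inside the window")
    res = stats.linregress(np.log(curve.q[mask]), np.log(curve.intensity[mask]))
    return -res.slope, res.stderr


def average_with_sem(values, ndigits: Optional[int] = None):
    """Mean and standard error (sample SD, n-1 denominator, over sqrt n).

    ``ndigits`` rounds both numbers for reporting.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values")
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    mean = arr.mean()
    sem = arr.std(ddof=1) / math.sqrt(arr.size)
    if ndigits is not None:
        mean, sem = round(mean, ndigits), round(sem, ndigits)
    return mean, sem
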