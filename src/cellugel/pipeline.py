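"""Per-condition orchestration, comparative summaries, and batch runs.

A :class:`ConditionSummary` collects the per-position stage outputs for
one synthesis condition (space or ground); :func:`compare_conditions`
derives the comparative quantities the study turns on — the ratio of mean
020 peak areas, the relative FWHM difference, the mean Rg2 with its
standard error, and the positional uniformity of the level-2 power-law
prefactor B2 (max/min across capillary positions). Derived numbers are
always recomputed from the stage outputs, never cached.

:func:`run_pipeline` drives a whole YAML-configured run (synthetic or
file inputs) and writes deterministic CSV tables plus a run log.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import fiberwidth, maldi, saxs, synth, tables, waxs
from .curves import read_curve, read_micrograph, read_spectrum

POSITIONS = ("upper", "middle", "bottom")


@dataclass
class ConditionSummary:
    """Stage outputs for one synthesis condition, keyed by capillary position."""

    condition: str
    waxs_020: dict = field(default_factory=dict)   # position -> {"area", "fwhm_deg"}
    rg2: dict = field(default_factory=dict)        # position -> nm
    b2: dict = field(default_factory=dict)         # position -> a.u.
    saxs_fits: dict = field(default_factory=dict)  # position -> UnifiedFitResult
    maldi_summary: Optional[maldi.DPSummary] = None
    diameter_stats: Optional[fiberwidth.DiameterStats] = None

    @classmethod
    def from_published(cls, condition: str) -> "ConditionSummary":
        """Summary built from the published tables (the built-in fixtures)."""
        w = tables.WAXS_020_TABLE
        rows = w[w.condition == condition]
        waxs_020 = {r.position: {"area": r.area, "fwhm_deg": r.fwhm_deg}
                    for r in rows.itertuples()}
        t2 = tables.unified_fit_table()
        rows2 = t2[t2.condition == condition]
        return cls(
            condition=condition,
            waxs_020=waxs_020,
            rg2={r.position: r.rg2 for r in rows2.itertuples()},
            b2={r.position: r.b2 for r in rows2.itertuples()},
            maldi_summary=None,
            diameter_stats=None,
        )

    # ---- derived quantities, recomputed on every access ----

    @property
    def mean_area(self) -> float:
        return waxs.summarize_positions({p: v["area"] for p, v in self.waxs_020.items()})

    @property
    def mean_fwhm_deg(self) -> float:
        return waxs.summarize_positions({p: v["fwhm_deg"] for p, v in self.waxs_020.items()})

    @property
    def rg2_mean_sem(self):
        return saxs.average_with_sem([self.rg2[p] for p in POSITIONS if p in self.rg2])

    @property
    def b2_uniformity(self) -> float:
        """Max/min ratio of B2 across positions (1 = perfectly uniform)."""
        vals = [self.b2[p] for p in POSITIONS if p in self.b2]
        if len(vals) < 2:
            raise ValueError("need B2 at two or more positions")
        return max(vals) / min(vals)


def compare_conditions(a: ConditionSummary, b: ConditionSummary) -> dict:
    """Comparative report between two conditions (by convention a=space, b=ground).

    Keys: ``area_ratio`` (b/a), ``fwhm_rel_diff`` ((b-a)/a), per-condition
    ``rg2_mean``/``rg2_sem``, ``b2_uniformity``, and when both sides carry
    them, MALDI mean DP and diameter means. A field missing on either side
    is omitted from the report with a warning, never silently zeroed.
    """
    report = {"condition_a": a.condition, "condition_b": b.condition}

    def _try(key, fn):
        try:
            report[key] = fn()
        except (ValueError, KeyError, TypeError, AttributeError) as exc:
            warnings.warn(f"comparison field {key!r} omitted: {exc}")

    _try("area_ratio", lambda: b.mean_area / a.mean_area)
    _try("fwhm_rel_diff", lambda: (b.mean_fwhm_deg - a.mean_fwhm_deg) / a.mean_fwhm_deg)
    for label, s in (("a", a), ("b", b)):
        _try(f"rg2_mean_{label}", lambda s=s: s.rg2_mean_sem[0])
        _try(f"rg2_sem_{label}", lambda s=s: s.rg2_mean_sem[1])
        _try(f"b2_uniformity_{label}", lambda s=s: s.b2_uniformity)
        _try(f"mean_dp_{label}", lambda s=s: s.maldi_summary.mean_dp)
        _try(f"diameter_mean_{label}", lambda s=s: s.diameter_stats.mean)
    return report


# ---------------------------------------------------------------------------
# config-driven batch run

_SCHEMA = {
    "seed": None,
    "conditions": {
        "*": {
            "saxs": {"source", "truth", "truth_from_table", "noise", "qmin",
                     "qmax", "n", "files", "init", "weighting"},
            "waxs": {"source", "peaks", "background", "noise", "n", "files",
                     "windows"},
            "maldi": {"source", "mean_dp", "dp_sigma", "dp_min", "dp_max",
                      "noise", "file", "adduct_mass"},
            "ribbons": {"source", "n_ribbons", "width_mean_um", "width_sd_um",
                        "width_um", "noise", "shape", "pixel_size_um", "file"},
        }
    },
}


def validate_config(config: dict) -> None:
    """Reject unknown keys, naming the offender."""
    for key in config:
        if key not in _SCHEMA:
            raise ValueError(f"unknown config key: {key!r}")
    for cond, stages in config.get("conditions", {}).items():
        for stage, opts in stages.items():
            if stage not in _SCHEMA["conditions"]["*"]:
                raise ValueError(f"unknown stage key: {cond}.{stage!r}")
            allowed = _SCHEMA["conditions"]["*"][stage]
            for opt in opts:
                if opt not in allowed:
                    raise ValueError(f"unknown stage key: {cond}.{stage}.{opt!r}")


def _condition_seed(seed: int, condition: str, stage: str, position: str = "") -> int:
    digest = hashlib.sha256(f"{seed}/{condition}/{stage}/{position}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


_DEFAULT_WAXS_PEAKS = [[8.69, 0.5, 120.0], [14.1, 0.45, 80.0], [15.6, 0.35, 200.0]]


def _run_saxs(cond: str, opts: dict, seed: int, log: dict) -> dict:
    fits = {}
    for pos in POSITIONS:
        if opts.get("source", "synthetic") == "files":
            curve = read_curve(opts["files"][pos], condition=cond, position=pos)
            init = saxs.UnifiedModelParams.from_dict(opts["init"])
        else:
            if "truth" in opts:
                truth = saxs.UnifiedModelParams.from_dict(opts["truth"])
            else:
                src_cond, src_pos = opts.get("truth_from_table", [cond, pos])
                truth = tables.unified_params_published(src_cond, src_pos)
            pos_seed = _condition_seed(seed, cond, "saxs", pos)
            log["seeds"][f"{cond}/saxs/{pos}"] = pos_seed
            cfg = synth.SynthConfig(
                kind="saxs", seed=pos_seed, noise=float(opts.get("noise", 0.02)),
                grid={"qmin": opts.get("qmin", 0.07), "qmax": opts.get("qmax", 2.5),
                      "n": opts.get("n", 300)},
                truth=truth.to_dict(),
            )
            curve = synth.generate_saxs_curve(cfg)
            rng = np.random.default_rng(pos_seed + 1)
            jitter = {k: v * rng.uniform(0.9, 1.1) for k, v in truth.to_dict().items()}
            jitter["rg1"] = max(jitter["rg1"], jitter["rg2"] * 1.5)
            jitter["p1"] = min(jitter["p1"], 8.0)
            jitter["p2"] = min(jitter["p2"], 8.0)
            init = saxs.UnifiedModelParams(**jitter)
        fits[pos] = saxs.fit_unified_model(curve, init,
                                           weighting=opts.get("weighting", "auto"))
    return fits


def _run_waxs(cond: str, opts: dict, seed: int, log: dict) -> dict:
    out = {}
    geometry = waxs.InstrumentGeometry()
    for pos in POSITIONS:
        if opts.get("source", "synthetic") == "files":
            profile = read_curve(opts["files"][pos], condition=cond, position=pos)
        else:
            pos_seed = _condition_seed(seed, cond, "waxs", pos)
            log["seeds"][f"{cond}/waxs/{pos}"] = pos_seed
            cfg = synth.SynthConfig(
                kind="waxs", seed=pos_seed, noise=float(opts.get("noise", 0.01)),
                truth={"peaks": opts.get("peaks", _DEFAULT_WAXS_PEAKS),
                       **({"background": opts["background"]} if "background" in opts else {})},
                grid={"n": opts.get("n", 600)},
            )
            profile = synth.generate_waxs_profile(cfg)
        windows = [tuple(w) for w in opts.get("windows", waxs.DEFAULT_PEAK_WINDOWS)]
        background = waxs.estimate_smooth_background(profile, windows)
        peaks = [p.with_angles(geometry) for p in waxs.fit_peaks(profile, background, windows)]
        out[pos] = waxs.assign_reflections(peaks)
    return out


def _run_maldi(cond: str, opts: dict, seed: int, log: dict):
    if opts.get("source", "synthetic") == "file":
        spectrum = read_spectrum(opts["file"], condition=cond)
    else:
        m_seed = _condition_seed(seed, cond, "maldi")
        log["seeds"][f"{cond}/maldi"] = m_seed
        truth = {k: opts[k] for k in ("mean_dp", "dp_sigma", "dp_min", "dp_max",
                                      "adduct_mass") if k in opts}
        cfg = synth.SynthConfig(kind="maldi", seed=m_seed,
                                noise=float(opts.get("noise", 0.02)), truth=truth)
        spectrum = synth.generate_maldi_spectrum(cfg)
    series = maldi.pick_series_peaks(spectrum,
                                     adduct_mass=float(opts.get("adduct_mass", maldi.ADDUCT_MASS)))
    return maldi.fit_gaussian_envelope(series)


def _run_ribbons(cond: str, opts: dict, seed: int, log: dict):
    if opts.get("source", "synthetic") == "file":
        image = read_micrograph(opts["file"], pixel_size=opts.get("pixel_size_um"),
                                condition=cond)
    else:
        r_seed = _condition_seed(seed, cond, "ribbons")
        log["seeds"][f"{cond}/ribbons"] = r_seed
        truth = {k: opts[k] for k in ("n_ribbons", "width_mean_um", "width_sd_um",
                                      "width_um") if k in opts}
        grid = {k: opts[k] for k in ("shape", "pixel_size_um") if k in opts}
        cfg = synth.SynthConfig(kind="ribbon_image", seed=r_seed,
                                noise=float(opts.get("noise", 0.0)),
                                truth=truth, grid=grid)
        image = synth.generate_ribbon_image(cfg)
    stats, _ = fiberwidth.analyze_micrograph(image)
    return stats


def run_pipeline(config, out_dir) -> dict:
    """Run every configured stage for every condition; write result tables.

    ``config`` is a YAML path or an already-parsed dict. Outputs under
    ``out_dir``: ``saxs_fits.csv``, ``waxs_table.csv``, ``maldi.csv``,
    ``fiber_stats.csv``, ``comparison.csv`` and ``run_log.json``. The run
    is deterministic: rerunning the same config reproduces byte-identical
    numeric tables.
    """
    if not isinstance(config, dict):
        path = Path(config)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        config = yaml.safe_load(path.read_text())
    validate_config(config)
    seed = int(config.get("seed", 0))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = {"seed": seed, "seeds": {},
           "config_sha256": hashlib.sha256(
               json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()}

    # fail fast on missing input files
    for cond, stages in config.get("conditions", {}).items():
        for stage, opts in stages.items():
            for f in list((opts.get("files") or {}).values()) + (
                    [opts["file"]] if "file" in opts else []):
                if not Path(f).exists():
                    raise FileNotFoundError(f"missing input file: {f}")

    summaries = {}
    saxs_rows, waxs_rows, maldi_rows, fiber_rows = [], [], [], []
    for cond, stages in config.get("conditions", {}).items():
        summary = ConditionSummary(condition=cond)
        if "saxs" in stages:
            fits = _run_saxs(cond, stages["saxs"], seed, log)
            summary.saxs_fits = fits
            summary.rg2 = {p: f.params.rg2 for p, f in fits.items()}
            summary.b2 = {p: f.params.b2 for p, f in fits.items()}
            for pos, f in fits.items():
                row = {"condition": cond, "position": pos,
                       "chi2_per_point": f.chi2_per_point, "converged": f.converged}
                row.update(f.params.to_dict())
                saxs_rows.append(row)
        if "waxs" in stages:
            assigned = _run_waxs(cond, stages["waxs"], seed, log)
            for pos, assignments in assigned.items():
                for a in assignments:
                    fwhm_deg_err = (a.peak.fwhm_q_err * a.peak.fwhm_2theta / a.peak.fwhm_q
                                    if a.peak.fwhm_q else float("nan"))
                    waxs_rows.append({
                        "condition": cond, "position": pos, "plane": a.plane_label,
                        "center_q": a.peak.center_q, "d_obs_A": a.d_obs,
                        "area": a.peak.area, "area_err": a.peak.area_err,
                        "fwhm_q": a.peak.fwhm_q, "fwhm_deg": a.peak.fwhm_2theta,
                        "fwhm_deg_err": fwhm_deg_err,
                    })
                    if a.plane_label == "020":
                        summary.waxs_020[pos] = {"area": a.peak.area,
                                                 "fwhm_deg": a.peak.fwhm_2theta}
            if len(summary.waxs_020) == 3:
                waxs_rows.append({
                    "condition": cond, "position": "average", "plane": "020",
                    "center_q": float("nan"), "d_obs_A": float("nan"),
                    "area": summary.mean_area, "area_err": float("nan"),
                    "fwhm_q": float("nan"), "fwhm_deg": summary.mean_fwhm_deg,
                    "fwhm_deg_err": float("nan"),
                })
        if "maldi" in stages:
            dp = _run_maldi(cond, stages["maldi"], seed, log)
            summary.maldi_summary = dp
            maldi_rows.append({"condition": cond, "mean_mw": dp.mean_mw,
                               "mean_dp": dp.mean_dp, "dp_min": dp.dp_min,
                               "dp_max": dp.dp_max,
                               "envelope_sigma": dp.envelope_sigma})
        if "ribbons" in stages:
            stats = _run_ribbons(cond, stages["ribbons"], seed, log)
            summary.diameter_stats = stats
            fiber_rows.append({"condition": cond, **stats.__dict__})
        summaries[cond] = summary

    if saxs_rows:
        pd.DataFrame(saxs_rows).to_csv(out_dir / "saxs_fits.csv", index=False)
    if waxs_rows:
        pd.DataFrame(waxs_rows).to_csv(out_dir / "waxs_table.csv", index=False)
    if maldi_rows:
        pd.DataFrame(maldi_rows).to_csv(out_dir / "maldi.csv", index=False)
    if fiber_rows:
        pd.DataFrame(fiber_rows).to_csv(out_dir / "fiber_stats.csv", index=False)

    report = {}
    conds = list(summaries)
    if len(conds) >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = compare_conditions(summaries[conds[0]], summaries[conds[1]])
        pd.DataFrame([report]).to_csv(out_dir / "comparison.csv", index=False)

    (out_dir / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True))
    return {"summaries": summaries, "comparison": report, "log": log}
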