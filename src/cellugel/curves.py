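"""Shared 1-D record types and plain-text I/O.

Scattering curves (SAXS and WAXS) and mass spectra are stored as
immutable-by-convention dataclasses wrapping numpy arrays, with small
plain-text readers/writers: whitespace- or comma-separated columns,
``#`` comment headers.  Q is in nm^-1 end-to-end; files in Å^-1 can be
converted on read with ``q_unit="angstrom"`` (× 10).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

#: capillary measurement positions and their offset from the capillary top (mm)
POSITION_OFFSETS_MM = {"upper": 10.0, "middle": 14.0, "bottom": 18.0}


def _as_1d_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be 1-D, got shape {arr.shape}")
    return arr


@dataclass
class ScatteringCurve:
    """A 1-D scattering record I(q), shared by the SAXS and WAXS stages.

    Parameters
    ----------
    q : array
        Scattering vector in nm^-1, strictly increasing, > 0.
    intensity : array
        Scattered intensity, arbitrary units.
    sigma : array, optional
        1-sigma uncertainties on the intensity (same units).
    condition : str
        Free label, e.g. ``"space"`` or ``"ground"``.
    position : str, optional
        Capillary position: ``"upper"``, ``"middle"`` or ``"bottom"``.
    meta : dict
        Free-form metadata (generator truth blocks, flags, ...).
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: Optional[np.ndarray] = None
    condition: str = ""
    position: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.q = _as_1d_float(self.q, "q")
        self.intensity = _as_1d_float(self.intensity, "intensity")
        if self.q.size < 10:
            raise ValueError("curve needs at least 10 points")
        if self.q.size != self.intensity.size:
            raise ValueError("q and intensity lengths differ")
        if np.any(self.q <= 0):
            raise ValueError("q must be strictly positive")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if self.sigma is not None:
            self.sigma = _as_1d_float(self.sigma, "sigma")
            if self.sigma.size != self.q.size:
                raise ValueError("sigma length differs from q")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be strictly positive")
        if self.position is not None and self.position not in POSITION_OFFSETS_MM:
            raise ValueError(f"unknown position {self.position!r}")

    def with_intensity(self, intensity, sigma=None) -> "ScatteringCurve":
        return replace(self, intensity=np.asarray(intensity, float), sigma=sigma)

    @property
    def position_offset_mm(self) -> Optional[float]:
        return POSITION_OFFSETS_MM.get(self.position) if self.position else None


@dataclass
class MassSpectrum:
    """A MALDI-ToF style (m/z, intensity) record.

    m/z in Da, strictly increasing; intensities >= 0 in arbitrary units.
    """

    mz: np.ndarray
    intensity: np.ndarray
    condition: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mz = _as_1d_float(self.mz, "mz")
        self.intensity = _as_1d_float(self.intensity, "intensity")
        if self.mz.size != self.intensity.size:
            raise ValueError("mz and intensity lengths differ")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("mz must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")


@dataclass
class Micrograph:
    """An 8-bit grayscale micrograph with a declared pixel size (µm/px)."""

    pixels: np.ndarray
    pixel_size: float
    condition: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if min(self.pixels.shape) < 64:
            raise ValueError("image must be at least 64x64 px")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


# ---------------------------------------------------------------------------
# text I/O


def _parse_header(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if body.startswith("truth="):
                meta["truth"] = json.loads(body[len("truth=") :])
            elif "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    return meta


def read_curve(path, q_unit: str = "nm", **kwargs) -> ScatteringCurve:
    """Read a 2- or 3-column text curve (q, I[, sigma]).

    ``q_unit="angstrom"`` converts Å^-1 → nm^-1 on read (× 10).
    '#'-prefixed header lines of the form ``key=value`` populate ``meta``.
    """
    path = Path(path)
    meta = _parse_header(path)
    data = np.loadtxt(path, comments="#", delimiter=None if _is_whitespace(path) else ",")
    if data.ndim != 2 or data.shape[1] not in (2, 3):
        raise ValueError(f"{path}: expected 2 or 3 columns")
    q = data[:, 0]
    if q_unit == "angstrom":
        q = q * 10.0
    elif q_unit != "nm":
        raise ValueError(f"unknown q unit {q_unit!r}")
    sigma = data[:, 2] if data.shape[1] == 3 else None
    kwargs.setdefault("condition", meta.get("condition", ""))
    kwargs.setdefault("position", meta.get("position") or None)
    return ScatteringCurve(q, data[:, 1], sigma, meta=meta, **kwargs)


def _is_whitespace(path: Path) -> bool:
    for line in open(path):
        if line.startswith("#") or not line.strip():
            continue
        return "," not in line
    return True


def write_curve(curve: ScatteringCurve, path) -> None:
    """Write a curve as tab-separated text with a '#' comment header."""
    cols = [curve.q, curve.intensity]
    if curve.sigma is not None:
        cols.append(curve.sigma)
    header = []
    if curve.condition:
        header.append(f"condition={curve.condition}")
    if curve.position:
        header.append(f"position={curve.position}")
    if "truth" in curve.meta:
        header.append("truth=" + json.dumps(curve.meta["truth"]))
    header.append("columns=q_nm^-1\tintensity" + ("\tsigma" if curve.sigma is not None else ""))
    np.savetxt(path, np.column_stack(cols), delimiter="\t", header="\n".join(header))


def read_spectrum(path, **kwargs) -> MassSpectrum:
    """Read a two-column (m/z, intensity) text spectrum."""
    path = Path(path)
    meta = _parse_header(path)
    data = np.loadtxt(path, comments="#", delimiter=None if _is_whitespace(path) else ",")
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 columns")
    kwargs.setdefault("condition", meta.get("condition", ""))
    return MassSpectrum(data[:, 0], data[:, 1], meta=meta, **kwargs)


def write_spectrum(spectrum: MassSpectrum, path) -> None:
    header = []
    if spectrum.condition:
        header.append(f"condition={spectrum.condition}")
    if "truth" in spectrum.meta:
        header.append("truth=" + json.dumps(spectrum.meta["truth"]))
    header.append("columns=mz_Da\tintensity")
    np.savetxt(
        path,
        np.column_stack([spectrum.mz, spectrum.intensity]),
        delimiter="\t",
        header="\n".join(header),
    )


def read_micrograph(path, pixel_size: Optional[float] = None, **kwargs) -> Micrograph:
    """Read an 8-bit PNG/TIFF micrograph.

    The pixel size (µm/px) is taken from a ``<name>.meta.json`` sidecar if
    present, else it must be passed explicitly.
    """
    import imageio.v3 as iio

    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if pixel_size is None:
        pixel_size = meta.get("pixel_size_um")
    if pixel_size is None:
        raise ValueError(f"{path}: no pixel size in sidecar and none given")
    img = iio.imread(path)
    if img.ndim == 3:  # collapse RGB(A) to grayscale
        img = img[..., :3].mean(axis=-1).astype(np.uint8)
    return Micrograph(img, float(pixel_size), meta=meta, **kwargs)


def write_micrograph(micrograph: Micrograph, path) -> None:
    """Write an 8-bit image plus a JSON sidecar carrying pixel size and truth."""
    import imageio.v3 as iio

    path = Path(path)
    iio.imwrite(path, micrograph.pixels.astype(np.uint8))
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = {"pixel_size_um": micrograph.pixel_size}
    meta.update(micrograph.meta)
    sidecar.write_text(json.dumps(meta, indent=1))
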