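"""File formats: spectrum CSV, chip configuration, image stacks, reports.

Frequencies are always serialised in Hz as decimal floats and responses are
unitless; parsers accept values with SI unit suffixes (``"10 mS/m"``,
``"6.5 um"``, ``"45 MHz"``) and normalise to SI internally.  Spectrum files
round-trip losslessly at 9 significant digits.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .densitometry import WellGeometry, WellImageSequence
from .dielectric import FrequencyGrid, Spectrum
from .fitting import FitResult
from .rhythm import CosinorFit, ParameterSeries

logger = logging.getLogger(__name__)

__all__ = [
    "parse_quantity",
    "read_spectrum",
    "write_spectrum",
    "read_parameter_series",
    "write_parameter_series",
    "ChipConfig",
    "read_chip_config",
    "write_chip_config",
    "write_image_sequence",
    "read_image_sequence",
    "write_png_frames",
    "read_png_frames",
    "format_fit_report",
    "format_cosinor_report",
]

# ---------------------------------------------------------------------------
# Quantities with unit suffixes
# ---------------------------------------------------------------------------

_PREFIXES = {
    "": 1.0, "f": 1e-15, "p": 1e-12, "n": 1e-9, "u": 1e-6, "µ": 1e-6,
    "m": 1e-3, "k": 1e3, "M": 1e6, "G": 1e9,
}
#: Recognised base units (dimension bookkeeping is left to the caller).
_BASE_UNITS = {"m", "Hz", "S/m", "F/m^2", "S/m^2", "F", "S", "V", "s", "h", ""}


def parse_quantity(text: str | float) -> float:
    """Parse ``"9.96 mF/m^2"`` / ``"45 MHz"`` / ``"6.5 um"`` to an SI float.

    Bare numbers (or numeric input) pass through unchanged.
    """
    if isinstance(text, (int, float)):
        return float(text)
    s = text.strip()
    match = re.fullmatch(r"([+-]?[\d.]+(?:[eE][+-]?\d+)?)\s*(\S*)", s)
    if match is None:
        raise ValueError(f"cannot parse quantity {text!r}")
    value, unit = float(match.group(1)), match.group(2)
    if unit in _BASE_UNITS:
        return value
    prefix, base = unit[:1], unit[1:]
    if prefix in _PREFIXES and base in _BASE_UNITS and base != "":
        return value * _PREFIXES[prefix]
    raise ValueError(f"unrecognised unit {unit!r} in {text!r}")


# ---------------------------------------------------------------------------
# Spectrum CSV
# ---------------------------------------------------------------------------

_SPECTRUM_HEADER = ["frequency_hz", "response", "sd", "n"]


def write_spectrum(spectrum: Spectrum, path) -> None:
    """Write a spectrum as ``frequency_hz,response[,sd,n]`` CSV."""
    path = Path(path)
    has_sd = spectrum.sd is not None
    cols = _SPECTRUM_HEADER[: 4 if has_sd else 2]
    lines = [",".join(cols)]
    n = spectrum.n_replicates if spectrum.n_replicates is not None else 1
    for i, (f, r) in enumerate(zip(spectrum.frequencies, spectrum.response)):
        row = [f"{f:.9g}", f"{r:.9g}"]
        if has_sd:
            row += [f"{spectrum.sd[i]:.9g}", str(n)]
        lines.append(",".join(row))
    path.write_text("\n".join(lines) + "\n")


def read_spectrum(path) -> Spectrum:
    """Read a spectrum CSV; malformed rows raise with their line number.

    Files with non-monotone frequencies are sorted with a warning; the sd
    and n columns are optional.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = [h.strip() for h in lines[0].split(",")]
    if header[:2] != _SPECTRUM_HEADER[:2]:
        raise ValueError(
            f"{path}:1: expected header starting 'frequency_hz,response', "
            f"got {lines[0]!r}"
        )
    has_sd = len(header) >= 3 and header[2] == "sd"
    freqs, resp, sds, ns = [], [], [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = [f.strip() for f in line.split(",")]
        try:
            freqs.append(float(fields[0]))
            resp.append(float(fields[1]))
            if has_sd:
                sds.append(float(fields[2]))
                if len(fields) > 3:
                    ns.append(int(fields[3]))
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed row {line!r}") from exc
    f = np.asarray(freqs)
    order = np.argsort(f, kind="stable")
    if not np.array_equal(order, np.arange(f.size)):
        logger.warning("%s: frequencies not monotone; sorting", path)
    f = f[order]
    r = np.asarray(resp)[order]
    sd = np.asarray(sds)[order] if has_sd else None
    n = ns[0] if ns else None
    return Spectrum(grid=FrequencyGrid(f), response=r, sd=sd, n_replicates=n)


# ---------------------------------------------------------------------------
# Parameter time series CSV (for cosinor analysis)
# ---------------------------------------------------------------------------

def write_parameter_series(series: ParameterSeries, path) -> None:
    path = Path(path)
    lines = ["time_h,value"]
    lines += [f"{t:.9g},{v:.9g}" for t, v in zip(series.times, series.values)]
    path.write_text("\n".join(lines) + "\n")


def read_parameter_series(path) -> ParameterSeries:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or [h.strip() for h in lines[0].split(",")][:2] != ["time_h", "value"]:
        raise ValueError(f"{path}:1: expected header 'time_h,value'")
    times, values = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        try:
            t, v = (float(x) for x in line.split(",")[:2])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed row {line!r}") from exc
        times.append(t)
        values.append(v)
    return ParameterSeries(times=np.asarray(times), values=np.asarray(values))


# ---------------------------------------------------------------------------
# Chip configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChipConfig:
    """Per-chip acquisition settings: the 20 well frequencies (Hz, each in
    1 kHz-45 MHz), peak-to-peak voltage (<= 20 V), run duration in seconds
    (10 s standard; 30 s for small particles such as platelets) and the
    medium conductivity in S/m."""

    well_frequencies: np.ndarray
    voltage: float = 10.0
    duration: float = 10.0
    medium_conductivity: float = 0.01

    def __post_init__(self) -> None:
        f = np.asarray(self.well_frequencies, dtype=float)
        if f.shape != (20,):
            raise ValueError("a chip has exactly 20 well frequencies")
        if np.any((f < 1e3 * (1 - 1e-9)) | (f > 45e6 * (1 + 1e-9))):
            raise ValueError("well frequencies must lie in [1 kHz, 45 MHz]")
        if not 0 < self.voltage <= 20:
            raise ValueError("voltage must be in (0, 20] V peak-to-peak")
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if self.medium_conductivity < 0:
            raise ValueError("medium conductivity must be >= 0")
        object.__setattr__(self, "well_frequencies", f)


def write_chip_config(config: ChipConfig, path) -> None:
    payload = {
        "well_frequencies_hz": [float(f) for f in config.well_frequencies],
        "voltage_vpp": config.voltage,
        "duration_s": config.duration,
        "medium_conductivity": f"{config.medium_conductivity} S/m",
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_chip_config(path) -> ChipConfig:
    payload = yaml.safe_load(Path(path).read_text())
    return ChipConfig(
        well_frequencies=np.asarray(payload["well_frequencies_hz"], dtype=float),
        voltage=parse_quantity(payload.get("voltage_vpp", 10.0)),
        duration=parse_quantity(payload.get("duration_s", 10.0)),
        medium_conductivity=parse_quantity(payload.get("medium_conductivity", 0.01)),
    )


# ---------------------------------------------------------------------------
# Image stacks
# ---------------------------------------------------------------------------

def write_image_sequence(sequence: WellImageSequence, path, bits: int = 16) -> None:
    """Write frames as a multi-frame grayscale TIFF plus a YAML sidecar.

    Float intensities in [0, 1] are scaled to the full 8- or 16-bit range;
    the sidecar (``<path>.yaml``) records geometry, timestamps and the
    intensity scale so reading is lossless up to quantisation.
    """
    if bits not in (8, 16):
        raise ValueError("bits must be 8 or 16")
    path = Path(path)
    peak = float(sequence.frames.max())
    scale = (2**bits - 1) / peak if peak > 0 else 1.0
    dtype = np.uint8 if bits == 8 else np.uint16
    data = np.clip(sequence.frames * scale, 0, 2**bits - 1).astype(dtype)
    tifffile.imwrite(path, data)
    geom = sequence.geometry
    sidecar = {
        "centre": [float(geom.centre[0]), float(geom.centre[1])],
        "radius": float(geom.radius),
        "frame_shape": [int(s) for s in geom.frame_shape],
        "n_rings": int(geom.n_rings),
        "timestamps_s": [float(t) for t in sequence.timestamps],
        "intensity_scale": scale,
    }
    path.with_suffix(path.suffix + ".yaml").write_text(
        yaml.safe_dump(sidecar, sort_keys=False))


def read_image_sequence(path) -> WellImageSequence:
    path = Path(path)
    sidecar = yaml.safe_load(path.with_suffix(path.suffix + ".yaml").read_text())
    data = tifffile.imread(path).astype(float) / sidecar["intensity_scale"]
    geometry = WellGeometry(
        centre=tuple(sidecar["centre"]),
        radius=sidecar["radius"],
        frame_shape=tuple(sidecar["frame_shape"]),
        n_rings=sidecar["n_rings"],
    )
    return WellImageSequence(
        frames=data,
        timestamps=np.asarray(sidecar["timestamps_s"], dtype=float),
        geometry=geometry,
    )


def write_png_frames(sequence: WellImageSequence, directory, bits: int = 16) -> None:
    """Write frames as numbered grayscale PNGs plus a YAML sidecar.

    Alternative to the multi-frame TIFF layout for tools that consume
    per-frame images; ``<directory>/geometry.yaml`` carries the metadata.
    """
    import imageio.v3 as iio

    if bits not in (8, 16):
        raise ValueError("bits must be 8 or 16")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    peak = float(sequence.frames.max())
    scale = (2**bits - 1) / peak if peak > 0 else 1.0
    dtype = np.uint8 if bits == 8 else np.uint16
    for i, frame in enumerate(sequence.frames):
        data = np.clip(frame * scale, 0, 2**bits - 1).astype(dtype)
        iio.imwrite(directory / f"frame_{i:04d}.png", data)
    geom = sequence.geometry
    sidecar = {
        "centre": [float(geom.centre[0]), float(geom.centre[1])],
        "radius": float(geom.radius),
        "frame_shape": [int(s) for s in geom.frame_shape],
        "n_rings": int(geom.n_rings),
        "timestamps_s": [float(t) for t in sequence.timestamps],
        "intensity_scale": scale,
    }
    (directory / "geometry.yaml").write_text(
        yaml.safe_dump(sidecar, sort_keys=False))


def read_png_frames(directory) -> WellImageSequence:
    import imageio.v3 as iio

    directory = Path(directory)
    sidecar = yaml.safe_load((directory / "geometry.yaml").read_text())
    paths = sorted(directory.glob("frame_*.png"))
    if not paths:
        raise ValueError(f"no frame_*.png files in {directory}")
    data = np.stack([iio.imread(p).astype(float) for p in paths])
    data /= sidecar["intensity_scale"]
    geometry = WellGeometry(
        centre=tuple(sidecar["centre"]),
        radius=sidecar["radius"],
        frame_shape=tuple(sidecar["frame_shape"]),
        n_rings=sidecar["n_rings"],
    )
    return WellImageSequence(
        frames=data,
        timestamps=np.asarray(sidecar["timestamps_s"], dtype=float),
        geometry=geometry,
    )


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def format_fit_report(result: FitResult) -> str:
    """Human-readable fit report: parameters with units, weights, scale,
    r-squared and a convergence block."""
    lines = ["DEP spectrum fit", "================"]
    for k, (cell, w) in enumerate(zip(result.components, result.weights), 1):
        lines += [
            f"population {k} (weight {w:.3f}):",
            f"  radius                  {cell.radius * 1e6:.3g} um (fixed unless freed)",
            f"  membrane capacitance    {cell.mem_capacitance * 1e3:.3g} mF/m^2",
            f"  membrane conductance    {cell.mem_conductance:.4g} S/m^2",
            f"  cytoplasm permittivity  {cell.cyt_rel_permittivity:.4g}",
            f"  cytoplasm conductivity  {cell.cyt_conductivity:.4g} S/m",
        ]
    lines += [
        f"scale alpha               {result.scale:.4g}",
        f"r^2 (Pearson, data vs model) {result.r_squared:.6f}",
        "convergence:",
        f"  converged  {result.converged}",
        f"  evaluations {result.iterations}",
        f"  residual sum of squares {result.cost:.6g}",
    ]
    if result.weight_degenerate:
        lines.append("warning: components indistinguishable; weights not "
                     "individually identifiable")
    return "\n".join(lines) + "\n"


def format_cosinor_report(fit: CosinorFit) -> str:
    return "\n".join([
        "Cosinor fit (fixed period)",
        "==========================",
        f"period     {fit.period:.4g} h (fixed)",
        f"mesor      {fit.mesor:.6g}",
        f"amplitude  {fit.amplitude:.6g}",
        f"acrophase  {fit.acrophase:.4f} rad",
        f"r^2 (1 - SSres/SStot) {fit.r_squared:.4f}",
    ]) + "\n"
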