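"""Seeded generators for every input the analysis pipeline consumes.

Synthetic spectra, rhythm series and (via :mod:`depwell.densitometry`) well
image sequences let every stage be exercised without the instrument.  The
default conditions mirror a typical experiment: 20 log-spaced frequencies
from 1 kHz to 45 MHz (about five per decade), additive Gaussian noise with
standard deviation 3% of the peak response, fifteen technical replicates
when averaging, and blood sampling every 30 minutes across 4 hours for
rhythm series.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .densitometry import simulate_well_sequence  # noqa: F401  (re-export)
from .dielectric import CellModel, FrequencyGrid, Medium, Mixture, Spectrum, dep_spectrum
from .rhythm import ParameterSeries

__all__ = [
    "NoiseModel",
    "DEFAULT_GRID",
    "generate_spectrum",
    "generate_rhythm_series",
    "preset",
    "list_presets",
    "jurkat_mixture",
    "simulate_well_sequence",
]

#: The instrument's usual frequency layout: 20 points, 1 kHz to 45 MHz.
DEFAULT_GRID = FrequencyGrid.log_spaced(1e3, 45e6, 20)

#: Default noise level as a fraction of the peak |response|.
DEFAULT_NOISE_SD_FRACTION = 0.03


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise with sd a fraction of the peak |response|."""

    sd_fraction: float = DEFAULT_NOISE_SD_FRACTION
    seed: int = 0
    kind: str = "additive-gaussian"

    def __post_init__(self) -> None:
        if self.sd_fraction < 0:
            raise ValueError("sd_fraction must be >= 0")
        if self.kind != "additive-gaussian":
            raise ValueError("only additive-gaussian noise is supported")


def generate_spectrum(
    cell_or_mixture,
    medium: Medium,
    grid: FrequencyGrid = DEFAULT_GRID,
    scale: float = 1.0,
    noise: NoiseModel | None = None,
    n_replicates: int = 1,
) -> list[Spectrum]:
    """Seeded replicate spectra from the forward model plus noise.

    With ``noise=None`` or ``sd_fraction=0`` each replicate reproduces the
    noiseless :func:`~depwell.dielectric.dep_spectrum` output exactly.
    """
    if n_replicates < 1:
        raise ValueError("need n_replicates >= 1")
    base = dep_spectrum(cell_or_mixture, medium, grid, scale=scale)
    if noise is None or noise.sd_fraction == 0:
        return [Spectrum(grid=grid, response=base.response.copy())
                for _ in range(n_replicates)]
    rng = np.random.default_rng(noise.seed)
    sd = noise.sd_fraction * float(np.max(np.abs(base.response)))
    return [
        Spectrum(grid=grid,
                 response=base.response + rng.normal(0.0, sd, size=len(grid)))
        for _ in range(n_replicates)
    ]


def generate_rhythm_series(
    mesor: float,
    amplitude: float,
    acrophase: float,
    period: float,
    t_start: float = 0.0,
    t_end: float = 4.0,
    dt: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ParameterSeries:
    """Cosine parameter time course y(t) = M + A cos(2 pi t/tau + phi).

    Defaults emulate the blood-sampling design: every 30 minutes from ZT0
    for 4 hours (9 points).  Zero ``noise_sd`` gives the exact cosine.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    times = np.arange(t_start, t_end + dt / 2.0, dt)
    values = mesor + amplitude * np.cos(2.0 * np.pi * times / period + acrophase)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=times.size)
    return ParameterSeries(times=times, values=values)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def _load_presets() -> dict:
    text = resources.files("depwell.data").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def list_presets() -> list[str]:
    """Names of the shipped cell/medium parameter presets."""
    return sorted(_load_presets())


def preset(name: str) -> tuple[CellModel, Medium]:
    """Load a named cell/medium preset (e.g. ``'jurkat_3dep'``)."""
    from .io import parse_quantity

    presets = _load_presets()
    if name not in presets:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(presets))}"
        )
    entry = presets[name]

    def q(value):
        return parse_quantity(value) if isinstance(value, str) else float(value)

    c = entry["cell"]
    cell = CellModel(
        radius=q(c["radius"]),
        mem_capacitance=q(c["mem_capacitance"]),
        mem_conductance=q(c["mem_conductance"]),
        cyt_rel_permittivity=q(c["cyt_rel_permittivity"]),
        cyt_conductivity=q(c["cyt_conductivity"]),
    )
    m = entry["medium"]
    medium = Medium(
        conductivity=q(m["conductivity"]),
        rel_permittivity=q(m["rel_permittivity"]),
    )
    return cell, medium


def jurkat_mixture(majority_weight: float = 0.9) -> tuple[Mixture, Medium]:
    """The benchmark two-population Jurkat sample: a healthy majority and a
    low-conductivity minority (defaults 90/10)."""
    healthy, medium = preset("jurkat_3dep")
    damaged, _ = preset("jurkat_minority")
    mix = Mixture((damaged, healthy),
                  np.array([1.0 - majority_weight, majority_weight]))
    return mix, medium
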