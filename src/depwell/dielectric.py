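"""Single-shell dielectric forward model for DEP well cytometry.

A cell in suspension is modelled as a conducting sphere (cytoplasm) wrapped
in one thin, poorly conducting shell (the plasma membrane).  Both the cell
compartments and the suspending medium are lossy dielectrics described by a
complex permittivity

    eps*(f) = eps0 * eps_r  -  j * sigma / (2 pi f)

The direction and magnitude of the dielectrophoretic force on the cell is
governed by the real part of the Clausius-Mossotti factor

    f_CM = (eps*_cell - eps*_med) / (eps*_cell + 2 eps*_med)

which for physical parameters lies in [-0.5, 1].  A measured DEP spectrum is
proportional to Re[f_CM] evaluated on the instrument's frequency grid; for a
heterogeneous sample it is the weight-averaged superposition of the factors
of the subpopulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

#: Vacuum permittivity, F/m.
EPS0 = 8.8541878128e-12

__all__ = [
    "EPS0",
    "Medium",
    "CellModel",
    "FrequencyGrid",
    "Spectrum",
    "Mixture",
    "complex_permittivity",
    "shelled_sphere_permittivity",
    "clausius_mossotti",
    "dep_spectrum",
    "crossover_frequencies",
]


@dataclass(frozen=True)
class Medium:
    """Suspending medium: relative permittivity and conductivity (S/m).

    The aqueous default ``rel_permittivity=78`` suits the sucrose/dextrose
    DEP media used with the instrument.
    """

    conductivity: float
    rel_permittivity: float = 78.0

    def __post_init__(self) -> None:
        if self.rel_permittivity < 1:
            raise ValueError("medium relative permittivity must be >= 1")
        if self.conductivity < 0:
            raise ValueError("medium conductivity must be >= 0")


@dataclass(frozen=True)
class CellModel:
    """Single-shell cell: geometry plus electrical parameters.

    Parameters
    ----------
    radius : float
        Cell radius in metres.
    mem_capacitance : float
        Specific membrane capacitance C_m in F/m^2.
    mem_conductance : float
        Specific membrane conductance G_m in S/m^2.
    cyt_rel_permittivity : float
        Relative permittivity of the cytoplasm.
    cyt_conductivity : float
        Cytoplasm conductivity in S/m.
    mem_thickness : float
        Membrane thickness d in metres; fixed at 5 nm by default and used
        only to convert the specific membrane parameters to shell
        properties (eps_r,mem = C_m d / eps0, sigma_mem = G_m d).  It is
        never a free fit parameter.
    """

    radius: float
    mem_capacitance: float
    mem_conductance: float
    cyt_rel_permittivity: float
    cyt_conductivity: float
    mem_thickness: float = 5e-9

    def __post_init__(self) -> None:
        if not self.mem_thickness > 0:
            raise ValueError("membrane thickness must be > 0")
        if not self.radius > self.mem_thickness:
            raise ValueError("radius must exceed membrane thickness")
        if not self.mem_capacitance > 0:
            raise ValueError("specific membrane capacitance must be > 0")
        if self.mem_conductance < 0:
            raise ValueError("specific membrane conductance must be >= 0")
        if self.cyt_conductivity < 0:
            raise ValueError("cytoplasm conductivity must be >= 0")
        if self.cyt_rel_permittivity < 1:
            raise ValueError("cytoplasm relative permittivity must be >= 1")

    @property
    def mem_rel_permittivity(self) -> float:
        """Shell relative permittivity derived from C_m and thickness."""
        return self.mem_capacitance * self.mem_thickness / EPS0

    @property
    def mem_conductivity(self) -> float:
        """Shell conductivity (S/m) derived from G_m and thickness."""
        return self.mem_conductance * self.mem_thickness


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing grid of positive frequencies in Hz."""

    frequencies: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.ndim != 1 or f.size == 0:
            raise ValueError("frequency grid must be a non-empty 1-D array")
        if np.any(f <= 0):
            raise ValueError("frequencies must be positive")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies", f)

    @classmethod
    def log_spaced(cls, f_min: float, f_max: float, n_points: int) -> "FrequencyGrid":
        """Log-spaced grid, the instrument's usual ~5 points/decade layout."""
        if not (0 < f_min < f_max):
            raise ValueError("need 0 < f_min < f_max")
        if n_points < 2:
            raise ValueError("need at least two points")
        return cls(np.logspace(np.log10(f_min), np.log10(f_max), n_points))

    def __len__(self) -> int:
        return int(self.frequencies.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrequencyGrid):
            return NotImplemented
        return np.array_equal(self.frequencies, other.frequencies)

    def __hash__(self):  # frozen dataclass w/ ndarray: identity hash is enough
        return id(self)


@dataclass(frozen=True)
class Spectrum:
    """A DEP spectrum: response (arbitrary polarisability units) on a grid.

    ``sd`` and ``n_replicates`` are optional per-point standard deviations
    and replicate counts (populated e.g. by replicate averaging).
    """

    grid: FrequencyGrid
    response: np.ndarray
    sd: np.ndarray | None = None
    n_replicates: int | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.response, dtype=float)
        if r.shape != (len(self.grid),):
            raise ValueError("response length must equal grid length")
        object.__setattr__(self, "response", r)
        if self.sd is not None:
            s = np.asarray(self.sd, dtype=float)
            if s.shape != r.shape:
                raise ValueError("sd length must equal grid length")
            if np.any(s < 0):
                raise ValueError("sd must be non-negative")
            object.__setattr__(self, "sd", s)

    @property
    def frequencies(self) -> np.ndarray:
        return self.grid.frequencies


@dataclass(frozen=True)
class Mixture:
    """Up to four cell subpopulations with simplex weights."""

    components: tuple[CellModel, ...]
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        if not 1 <= len(comps) <= 4:
            raise ValueError("mixture must have between 1 and 4 components")
        object.__setattr__(self, "components", comps)
        if self.weights is None:
            w = np.full(len(comps), 1.0 / len(comps))
        else:
            w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(comps),):
            raise ValueError("one weight per component required")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        total = w.sum()
        if not np.isclose(total, 1.0, rtol=0, atol=1e-9):
            raise ValueError("weights must sum to 1")
        object.__setattr__(self, "weights", w / total)


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def complex_permittivity(
    rel_permittivity: float, conductivity: float, frequency
) -> complex | np.ndarray:
    """Complex permittivity eps* = eps0 eps_r - j sigma/(2 pi f), in F/m.

    ``frequency`` may be a scalar or array of positive values in Hz.
    """
    f = np.asarray(frequency, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    out = EPS0 * rel_permittivity - 1j * conductivity / (2.0 * np.pi * f)
    out = np.asarray(out)
    return out if out.ndim else complex(out)


def shelled_sphere_permittivity(cell: CellModel, frequency) -> complex | np.ndarray:
    """Effective complex permittivity of a single-shell sphere.

    Uses the standard concentric-shell reduction

        eps*_cell = eps*_mem (g^3 + 2 Phi) / (g^3 - Phi),
        g = r / (r - d),  Phi = (eps*_cyt - eps*_mem) / (eps*_cyt + 2 eps*_mem)

    where the shell (membrane) permittivity/conductivity are derived from
    the specific membrane capacitance and conductance via the membrane
    thickness.
    """
    eps_mem = complex_permittivity(
        cell.mem_rel_permittivity, cell.mem_conductivity, frequency
    )
    eps_cyt = complex_permittivity(
        cell.cyt_rel_permittivity, cell.cyt_conductivity, frequency
    )
    g3 = (cell.radius / (cell.radius - cell.mem_thickness)) ** 3
    phi = (eps_cyt - eps_mem) / (eps_cyt + 2.0 * eps_mem)
    return eps_mem * (g3 + 2.0 * phi) / (g3 - phi)


def clausius_mossotti(cell: CellModel, medium: Medium, frequency) -> complex | np.ndarray:
    """Clausius-Mossotti factor f_CM of a single-shell cell in a medium."""
    eps_cell = shelled_sphere_permittivity(cell, frequency)
    eps_med = complex_permittivity(
        medium.rel_permittivity, medium.conductivity, frequency
    )
    return (eps_cell - eps_med) / (eps_cell + 2.0 * eps_med)


def _as_mixture(cell_or_mixture) -> Mixture:
    if isinstance(cell_or_mixture, Mixture):
        return cell_or_mixture
    if isinstance(cell_or_mixture, CellModel):
        return Mixture((cell_or_mixture,), np.array([1.0]))
    raise TypeError("expected a CellModel or Mixture")


def dep_spectrum(
    cell_or_mixture,
    medium: Medium,
    grid: FrequencyGrid,
    scale: float = 1.0,
) -> Spectrum:
    """Model DEP spectrum: scale * sum_k w_k Re[f_CM,k] on the grid.

    For a heterogeneous sample the measured spectrum is the superposition
    of the Clausius-Mossotti factors of the subpopulations, weighted by
    their number fractions; ``scale`` is the instrument proportionality
    factor between Re[f_CM] and the recorded polarisability units.
    """
    if not scale > 0:
        raise ValueError("scale must be positive")
    mix = _as_mixture(cell_or_mixture)
    f = grid.frequencies
    response = np.zeros_like(f)
    for cell, w in zip(mix.components, mix.weights):
        response += w * np.real(clausius_mossotti(cell, medium, f))
    return Spectrum(grid=grid, response=scale * response)


def crossover_frequencies(
    cell: CellModel,
    medium: Medium,
    f_min: float,
    f_max: float,
    n_scan: int = 4000,
    tol: float = 1e-6,
) -> list[float]:
    """Frequencies in (f_min, f_max) where Re[f_CM] changes sign.

    A dense logarithmic scan locates sign changes which are then refined by
    Brent root bracketing.  Returns an ordered (possibly empty) list; at
    each returned frequency |Re[f_CM]| < ``tol``.
    """
    if not f_min < f_max:
        raise ValueError("need f_min < f_max")
    freqs = np.logspace(np.log10(f_min), np.log10(f_max), n_scan)
    vals = np.real(clausius_mossotti(cell, medium, freqs))
    if np.max(np.abs(vals)) < 1e-9:
        # everywhere-zero within numerical noise (cell matches medium)
        return []
    roots: list[float] = []
    sign = np.sign(vals)
    for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        root = brentq(
            lambda f: float(np.real(clausius_mossotti(cell, medium, f))),
            freqs[i],
            freqs[i + 1],
            xtol=1e-3,
            rtol=1e-14,
        )
        if abs(float(np.real(clausius_mossotti(cell, medium, root)))) < tol:
            if not roots or abs(root - roots[-1]) > 1e-6 * root:
                roots.append(float(root))
    return sorted(roots)
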