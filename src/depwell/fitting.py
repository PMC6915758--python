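"""Spectrum fitting: recover cell electrical parameters from DEP spectra.

The inverse problem — given a measured polarisability spectrum, find the
single-shell parameters (and, for heterogeneous samples, subpopulation
weights) whose superposed Clausius-Mossotti factors reproduce it — is solved
by damped least squares (Levenberg-Marquardt, via :mod:`lmfit`).

Conventions adopted here:

* the cell radius is fixed from an independent optical measurement by
  default (it can be freed);
* strictly positive parameters (C_m, G_m, sigma_cyt, the instrument scale
  alpha) are fitted as log10 values, which enforces positivity and suits
  spectra spanning four decades of frequency;
* mixture weights live on the simplex (sum to one) via fixed-anchor logits,
  so the global scale alpha stays identifiable;
* the objective is unweighted least squares, switching to inverse-variance
  weights when the spectrum carries per-point standard deviations;
* fits restart from several log-uniform initial guesses (seeded) and the
  lowest final residual wins;
* goodness of fit is the squared Pearson correlation between data and
  model, the convention used for instrument spectra.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import lmfit
import numpy as np

from .dielectric import CellModel, FrequencyGrid, Medium, Mixture, Spectrum, dep_spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "FitConfig",
    "FitResult",
    "average_spectra",
    "goodness_of_fit",
    "fit_single_population",
    "fit_mixture",
    "plan_interleaved_frequencies",
    "merge_interleaved",
]

#: Parameters that may be freed per population, with default (lo, hi) bounds.
#: The bounds double as a physical prior: a 20-point spectrum constrains a
#: single-shell cell only up to a discrete "swapped-interface" ambiguity
#: (a highly conductive membrane around a near-insulating, high-permittivity
#: core reproduces the same two dispersions), and restricting the search to
#: living-cell ranges selects the physical branch.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "mem_capacitance": (1e-3, 1e-1),        # F/m^2 (1-100 mF/m^2)
    "mem_conductance": (1e-2, 2e5),         # S/m^2 (up to ~200 kS/m^2)
    "cyt_conductivity": (1e-2, 2.5),        # S/m
    "cyt_rel_permittivity": (20.0, 150.0),  # dimensionless
    "radius": (1e-7, 5e-5),                 # m
    "scale": (1e-6, 1e6),                   # instrument units per unit Re[f_CM]
}

#: Parameters fitted on a log10 scale (strictly positive, wide-ranged).
_LOG_PARAMS = {"mem_capacitance", "mem_conductance", "cyt_conductivity", "radius", "scale"}

_DEFAULT_FREE = {
    "mem_capacitance": True,
    "mem_conductance": True,
    "cyt_conductivity": True,
    "cyt_rel_permittivity": True,
    "radius": False,
}


@dataclass(frozen=True)
class FitConfig:
    """Hyperparameters of a spectrum fit.

    ``free`` maps parameter names to whether they are fitted (radius fixed
    by default); ``fixed_values`` optionally pins a fixed parameter to a
    value other than the initial guess; ``bounds`` overrides entries of
    :data:`DEFAULT_BOUNDS`.
    """

    n_populations: int = 1
    free: dict[str, bool] = field(default_factory=lambda: dict(_DEFAULT_FREE))
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    fixed_values: dict[str, float] = field(default_factory=dict)
    initial: dict[str, float] = field(default_factory=dict)
    scale_free: bool = True
    max_iterations: int = 2000
    tolerance: float = 1e-12
    n_restarts: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_populations <= 4:
            raise ValueError("n_populations must be between 1 and 4")
        merged = {**DEFAULT_BOUNDS, **self.bounds}
        for name, (lo, hi) in merged.items():
            if not lo < hi:
                raise ValueError(f"bounds for {name!r} must satisfy lower < upper")
        object.__setattr__(self, "bounds", merged)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a spectrum fit.

    ``weight_degenerate`` flags mixtures whose recovered components are
    indistinguishable, in which case the individual weights carry no
    information (only their sum does).
    """

    components: tuple[CellModel, ...]
    weights: np.ndarray
    scale: float
    r_squared: float
    residuals: np.ndarray
    converged: bool
    iterations: int
    cost: float
    weight_degenerate: bool = False

    @property
    def mixture(self) -> Mixture:
        return Mixture(self.components, self.weights)


# ---------------------------------------------------------------------------
# Replicate averaging and goodness of fit
# ---------------------------------------------------------------------------

def average_spectra(spectra: list[Spectrum]) -> Spectrum:
    """Average replicate spectra sharing one frequency grid.

    Returns the per-frequency mean with the sample standard deviation (over
    replicates) and the replicate count attached.
    """
    if not spectra:
        raise ValueError("no spectra to average")
    grid = spectra[0].grid
    for s in spectra[1:]:
        if s.grid != grid:
            raise ValueError("all spectra must share one frequency grid")
    stack = np.stack([s.response for s in spectra])
    n = stack.shape[0]
    sd = stack.std(axis=0, ddof=1) if n > 1 else np.zeros(stack.shape[1])
    return Spectrum(grid=grid, response=stack.mean(axis=0), sd=sd, n_replicates=n)


def goodness_of_fit(observed: Spectrum, modelled: Spectrum) -> float:
    """Squared Pearson correlation between observed and modelled responses.

    Returns NaN when the observed response has zero variance (undefined).
    """
    if observed.grid != modelled.grid:
        raise ValueError("observed and modelled spectra must share a grid")
    x, y = observed.response, modelled.response
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2)


# ---------------------------------------------------------------------------
# Parameter plumbing
# ---------------------------------------------------------------------------

def _add_param(params: lmfit.Parameters, name: str, value: float,
               lo: float, hi: float, free: bool) -> None:
    base = name.rsplit("__", 1)[0]
    if base in _LOG_PARAMS:
        params.add(f"log_{name}", value=np.log10(value),
                   min=np.log10(lo), max=np.log10(hi), vary=free)
    else:
        params.add(name, value=value, min=lo, max=hi, vary=free)


def _get_param(params, name: str) -> float:
    base = name.rsplit("__", 1)[0]
    if base in _LOG_PARAMS:
        return 10.0 ** params[f"log_{name}"].value
    return params[name].value


def _cells_from_params(params, radii, config: FitConfig, mem_thickness: float):
    cells = []
    for k in range(len(radii)):
        cells.append(
            CellModel(
                radius=_get_param(params, f"radius__{k}"),
                mem_capacitance=_get_param(params, f"mem_capacitance__{k}"),
                mem_conductance=_get_param(params, f"mem_conductance__{k}"),
                cyt_rel_permittivity=_get_param(params, f"cyt_rel_permittivity__{k}"),
                cyt_conductivity=_get_param(params, f"cyt_conductivity__{k}"),
                mem_thickness=mem_thickness,
            )
        )
    return cells


def _weights_from_params(params, n_pop: int) -> np.ndarray:
    if n_pop == 1:
        return np.array([1.0])
    logits = np.array([0.0] + [params[f"wlogit__{k}"].value for k in range(1, n_pop)])
    e = np.exp(logits - logits.max())
    return e / e.sum()


def _initial_values(rng: np.random.Generator, config: FitConfig,
                    names: list[str]) -> dict[str, float]:
    """Log-uniform draw within bounds for every varying parameter."""
    out = {}
    for name in names:
        lo, hi = config.bounds[name.rsplit("__", 1)[0]]
        if name.rsplit("__", 1)[0] in _LOG_PARAMS:
            out[name] = 10.0 ** rng.uniform(np.log10(lo), np.log10(hi))
        else:
            out[name] = rng.uniform(lo, hi)
    return out


def _run_fit(spectrum: Spectrum, medium: Medium, radii, config: FitConfig,
             mem_thickness: float = 5e-9) -> FitResult:
    """Shared engine behind single-population and mixture fits."""
    n_pop = len(radii)
    f = spectrum.frequencies
    data = spectrum.response
    if spectrum.sd is not None and np.all(spectrum.sd > 0):
        weights = 1.0 / spectrum.sd
    else:
        weights = None

    def residual(params):
        cells = _cells_from_params(params, radii, config, mem_thickness)
        w = _weights_from_params(params, n_pop)
        mix = Mixture(tuple(cells), w)
        scale = _get_param(params, "scale") if config.scale_free else \
            config.fixed_values.get("scale", 1.0)
        model = dep_spectrum(mix, medium, spectrum.grid, scale=scale).response
        res = model - data
        return res * weights if weights is not None else res

    per_pop_names = ["mem_capacitance", "mem_conductance",
                     "cyt_conductivity", "cyt_rel_permittivity", "radius"]

    def build_params(init: dict[str, float]) -> lmfit.Parameters:
        params = lmfit.Parameters()
        for k in range(n_pop):
            for base in per_pop_names:
                name = f"{base}__{k}"
                lo, hi = config.bounds[base]
                if base == "radius" and not config.free.get("radius", False):
                    value, free = radii[k], False
                else:
                    free = config.free.get(base, True)
                    if not free:
                        value = config.fixed_values.get(
                            name, config.fixed_values.get(base, np.sqrt(lo * hi)))
                    else:
                        value = init.get(
                            name,
                            config.initial.get(
                                name,
                                config.initial.get(base, np.sqrt(lo * hi))))
                _add_param(params, name, value, lo, hi, free)
        lo, hi = config.bounds["scale"]
        scale0 = init.get("scale", config.initial.get(
            "scale", config.fixed_values.get("scale", 1.0)))
        _add_param(params, "scale", np.clip(scale0, lo, hi), lo, hi,
                   config.scale_free)
        for k in range(1, n_pop):
            params.add(f"wlogit__{k}",
                       value=init.get(f"wlogit__{k}",
                                      config.initial.get(f"wlogit__{k}", 0.0)),
                       min=-12.0, max=12.0, vary=True)
        return params

    varying = []
    for k in range(n_pop):
        for base in per_pop_names:
            if base == "radius" and not config.free.get("radius", False):
                continue
            if config.free.get(base, True):
                varying.append(f"{base}__{k}")
    varying.append("scale")  # scale restarts drawn within bounds too

    rng = np.random.default_rng(config.seed)
    starts: list[dict[str, float]] = [{}]  # bound-midpoint / default start
    for _ in range(max(config.n_restarts - 1, 0)):
        init = _initial_values(rng, config, varying)
        for k in range(1, n_pop):
            init[f"wlogit__{k}"] = rng.uniform(-2.0, 2.0)
        starts.append(init)

    def minimize_once(params):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = lmfit.minimize(
                residual, params, method="leastsq",
                max_nfev=config.max_iterations,
                xtol=config.tolerance, ftol=config.tolerance,
            )
        return float(np.sum(np.asarray(out.residual) ** 2)), out

    def minimize_from(params, max_rounds: int = 4):
        # MINPACK tends to stop prematurely in the ill-conditioned valleys
        # these spectra produce; restarting from the incumbent resets its
        # internal scaling and frequently resumes the descent.
        cost, out = minimize_once(params)
        for _ in range(max_rounds - 1):
            new_cost, new_out = minimize_once(out.params.copy())
            if not new_cost < cost * (1.0 - 1e-9):
                if new_cost < cost:
                    cost, out = new_cost, new_out
                break
            cost, out = new_cost, new_out
        return cost, out

    best = None
    for init in starts:
        try:
            cost, out = minimize_from(build_params(init))
        except Exception as exc:  # pathological start: keep going
            logger.debug("restart failed: %s", exc)
            continue
        if best is None or cost < best[0]:
            best = (cost, out)

    if best is None:
        raise RuntimeError("all fit restarts failed")

    # Polish: damped least squares stalls on the floor of the curved,
    # ill-conditioned valley these spectra produce (sloppy C_m/G_m/alpha
    # combinations).  Two complementary escapes are alternated: a
    # warm-started profile walk along each parameter and plain coordinate
    # jumps, both keeping only fully re-optimised improvements.
    for _ in range(2):
        before = best[0]
        best = _profile_polish(best, minimize_from)
        best = _jump_polish(best, minimize_from)
        if not best[0] < before * (1.0 - 1e-9):
            break
    cost, out = best

    cells = _cells_from_params(out.params, radii, config, mem_thickness)
    w = _weights_from_params(out.params, n_pop)
    scale = _get_param(out.params, "scale") if config.scale_free else \
        config.fixed_values.get("scale", 1.0)

    # canonical component order: ascending cytoplasm conductivity
    order = np.argsort([c.cyt_conductivity for c in cells], kind="stable")
    cells = [cells[i] for i in order]
    w = w[order]

    degenerate = _weights_degenerate(cells)
    if degenerate:
        logger.warning(
            "mixture components are indistinguishable; individual weights "
            "are not identifiable"
        )

    model = dep_spectrum(Mixture(tuple(cells), w), medium, spectrum.grid,
                         scale=scale)
    r2 = goodness_of_fit(spectrum, model)
    return FitResult(
        components=tuple(cells),
        weights=w,
        scale=float(scale),
        r_squared=r2,
        residuals=model.response - data,
        converged=bool(out.success),
        iterations=int(out.nfev),
        cost=cost,
        weight_degenerate=degenerate,
    )


def _profile_polish(best, minimize_from, max_rounds: int = 2,
                    max_steps: int = 12, cost_floor: float = 1e-24):
    """Valley-walking refinement around the incumbent solution.

    Scans each free parameter in both directions (0.25 steps for
    log/logit-scaled parameters, 5% of the bound range for linear ones),
    holding it fixed while the remaining parameters are re-optimised from
    the previous point, and keeps the best fully-freed refit encountered.
    A direction is abandoned after two consecutive non-improving profile
    steps; the scan stops once the residual is at numerical zero.
    """
    for _ in range(max_rounds):
        improved_any = False
        free_names = [n for n, p in best[1].params.items() if p.vary]
        for name in free_names:
            if best[0] < cost_floor:
                return best
            ref = best[1].params[name]
            step0 = 0.25 if name.startswith(("log_", "wlogit")) else \
                0.05 * (ref.max - ref.min)
            for sign in (1.0, -1.0):
                current = best
                profile_cost = best[0]
                bad = 0
                for _k in range(max_steps):
                    params = current[1].params.copy()
                    p = params[name]
                    new_val = np.clip(p.value + sign * step0, p.min, p.max)
                    if new_val == p.value:
                        break
                    p.set(value=new_val, vary=False)
                    try:
                        cost, out = minimize_from(params, max_rounds=2)
                    except Exception:
                        break
                    out.params[name].set(vary=True)
                    current = (cost, out)
                    if cost < best[0] * (1.0 - 1e-9):
                        refit_cost, refit_out = minimize_from(out.params.copy())
                        if refit_cost < best[0]:
                            best = (refit_cost, refit_out)
                            improved_any = True
                    if cost < profile_cost * (1.0 - 1e-9):
                        profile_cost = cost
                        bad = 0
                    else:
                        bad += 1
                        if bad >= 2:
                            break
        if not improved_any:
            break
    return best


def _jump_polish(best, minimize_from, cost_floor: float = 1e-24):
    """Single coordinate jumps (fractions of a decade for log-scaled
    parameters) away from the incumbent, each followed by a full refit;
    keeps any improvement.  Complements the profile walk: a jump can hop
    over a ridge directly into the global basin."""
    if best[0] < cost_floor:
        return best
    improved = True
    cycles = 0
    while improved and cycles < 2:
        improved = False
        cycles += 1
        free_names = [n for n, p in best[1].params.items() if p.vary]
        for name in free_names:
            if best[0] < cost_floor:
                return best
            ref = best[1].params[name]
            scale = 1.0 if name.startswith(("log_", "wlogit")) else \
                0.2 * (ref.max - ref.min)
            for step in (0.3, -0.3, 1.0, -1.0):
                params = best[1].params.copy()
                p = params[name]
                p.set(value=np.clip(p.value + step * scale, p.min, p.max))
                try:
                    cost, out = minimize_from(params)
                except Exception:
                    continue
                if cost < best[0] * (1.0 - 1e-9):
                    best = (cost, out)
                    improved = True
    return best


def _weights_degenerate(cells, rtol: float = 0.01) -> bool:
    """True when any two components agree in every parameter within rtol."""
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            a, b = cells[i], cells[j]
            pairs = [
                (a.radius, b.radius),
                (a.mem_capacitance, b.mem_capacitance),
                (a.mem_conductance, b.mem_conductance),
                (a.cyt_rel_permittivity, b.cyt_rel_permittivity),
                (a.cyt_conductivity, b.cyt_conductivity),
            ]
            if all(abs(x - y) <= rtol * max(abs(x), abs(y), 1e-300)
                   for x, y in pairs):
                return True
    return False


# ---------------------------------------------------------------------------
# Public fit entry points
# ---------------------------------------------------------------------------

def fit_single_population(spectrum: Spectrum, medium: Medium, radius: float,
                          config: FitConfig | None = None) -> FitResult:
    """Fit the single-shell model to a spectrum of a homogeneous sample.

    ``radius`` comes from an independent optical measurement and stays
    fixed unless ``config.free['radius']`` is set.  The spectrum must have
    at least 6 points spanning at least two decades of frequency.
    """
    config = config or FitConfig()
    f = spectrum.frequencies
    if f.size < 6 or f[-1] / f[0] < 100:
        raise ValueError("spectrum must have >= 6 points spanning >= 2 decades")
    return _run_fit(spectrum, medium, [radius], config)


def fit_mixture(spectrum: Spectrum, medium: Medium, radii,
                config: FitConfig | None = None) -> FitResult:
    """Fit a superposition of up to four single-shell subpopulations.

    One radius per component; weights are constrained to the simplex and
    the recovered components are reported in ascending cytoplasm
    conductivity so that populations are comparable across runs.  With a
    single radius this reduces exactly to :func:`fit_single_population`.
    """
    radii = list(radii)
    if not 1 <= len(radii) <= 4:
        raise ValueError("between 1 and 4 component radii required")
    config = config or FitConfig(n_populations=len(radii))
    if len(radii) != config.n_populations:
        config = replace(config, n_populations=len(radii))
    if len(radii) == 1:
        return fit_single_population(spectrum, medium, radii[0], config)
    f = spectrum.frequencies
    if f.size < 6 or f[-1] / f[0] < 100:
        raise ValueError("spectrum must have >= 6 points spanning >= 2 decades")
    return _run_fit(spectrum, medium, radii, config)


# ---------------------------------------------------------------------------
# Interleaved high-resolution spectra
# ---------------------------------------------------------------------------

def plan_interleaved_frequencies(
    f_min: float, f_max: float, n_points: int, n_chips: int
) -> tuple[list[FrequencyGrid], float]:
    """Frequency plans for synthesising a high-resolution spectrum from
    several chips.

    Chip 0 carries the base ``n_points`` log-spaced grid from ``f_min`` to
    ``f_max``; each successive chip's grid is the previous one multiplied
    by a constant shift factor equal to the adjacent-point ratio to the
    power 1/n_chips, so the merged grids form one uniformly log-spaced grid
    of n_points * n_chips frequencies.  Returns (grids, shift_factor).

    For 20 points spanning 1 kHz-40 MHz over 5 chips the factor is 1.118
    (1 kHz-45 MHz gives 1.119).
    """
    if n_points < 2:
        raise ValueError("need n_points >= 2")
    if n_chips < 1:
        raise ValueError("need n_chips >= 1")
    base = FrequencyGrid.log_spaced(f_min, f_max, n_points)
    ratio = (f_max / f_min) ** (1.0 / (n_points - 1))
    factor = ratio ** (1.0 / n_chips)
    grids = [
        FrequencyGrid(base.frequencies * factor**c) for c in range(n_chips)
    ]
    return grids, factor


def merge_interleaved(spectra: list[Spectrum]) -> Spectrum:
    """Merge spectra measured on shifted grids into one sorted spectrum.

    Duplicate frequencies are collapsed to their mean with a warning.  A
    single input is returned unchanged.
    """
    if not spectra:
        raise ValueError("no spectra to merge")
    if len(spectra) == 1:
        return spectra[0]
    f = np.concatenate([s.frequencies for s in spectra])
    r = np.concatenate([s.response for s in spectra])
    order = np.argsort(f, kind="stable")
    f, r = f[order], r[order]
    dup = np.isclose(np.diff(f), 0.0, rtol=1e-12, atol=0.0)
    if np.any(dup):
        logger.warning("duplicate frequencies in interleaved merge; "
                       "collapsing to the mean")
        uniq_f, inverse = np.unique(f, return_inverse=True)
        sums = np.bincount(inverse, weights=r)
        counts = np.bincount(inverse)
        f, r = uniq_f, sums / counts
    return Spectrum(grid=FrequencyGrid(f), response=r)
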