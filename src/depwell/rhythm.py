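"""Fixed-period cosinor analysis of electrophysiological time series.

Blood parameters sampled repeatedly over a few hours (e.g. cytoplasm
conductivity every 30 min across 4 h) are tested for an ultradian rhythm by
fitting a cosine of *fixed* period tau — taken from independently observed
behavioural activity, never fitted — with mesor M, amplitude A and acrophase
phi free:

    y(t) = M + A cos(2 pi t / tau + phi)

The model is linear in (M, beta, gamma) after expanding the cosine, so the
fit is a closed-form ordinary least-squares solve with
A = sqrt(beta^2 + gamma^2) and phi = atan2(-gamma, beta), wrapped to
[0, 2 pi).  Goodness of fit is the non-linear coefficient of determination
r^2 = 1 - SSres/SStot (distinct from the squared Pearson correlation used
for spectrum fits).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["ParameterSeries", "CosinorFit", "cosinor_fit", "counterphase_check"]


@dataclass(frozen=True)
class ParameterSeries:
    """A fitted-parameter time course: times in hours (e.g. Zeitgeber Time),
    values in the parameter's units, with optional per-point sd and n."""

    times: np.ndarray
    values: np.ndarray
    sd: np.ndarray | None = None
    n: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be matching 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class CosinorFit:
    """Cosinor parameters: mesor, amplitude (>= 0), acrophase in [0, 2 pi),
    the fixed period in hours, and the residual-based r^2 (NaN when the
    series has zero variance)."""

    mesor: float
    amplitude: float
    acrophase: float
    period: float
    r_squared: float


def cosinor_fit(series: ParameterSeries, period: float) -> CosinorFit:
    """Least-squares cosinor with the period fixed by the caller.

    Requires at least 4 points for the 3-parameter model; warns when the
    series spans less than one full period.
    """
    if not period > 0:
        raise ValueError("period must be positive")
    t, y = series.times, series.values
    if t.size < 4:
        raise ValueError("need at least 4 points for a 3-parameter cosinor")
    if t[-1] - t[0] < period:
        logger.warning(
            "series spans %.3g h, less than one period (%.3g h); "
            "amplitude and phase may be poorly constrained",
            t[-1] - t[0],
            period,
        )
    omega = 2.0 * math.pi / period
    design = np.column_stack([np.ones_like(t), np.cos(omega * t), np.sin(omega * t)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    mesor, beta, gamma = (float(c) for c in coef)
    amplitude = math.hypot(beta, gamma)
    acrophase = math.atan2(-gamma, beta) % (2.0 * math.pi)
    fitted = design @ coef
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = math.nan if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CosinorFit(mesor, amplitude, acrophase, float(period), r2)


def counterphase_check(fit_a: CosinorFit, fit_b: CosinorFit) -> tuple[float, bool]:
    """Wrapped acrophase difference and whether the two rhythms are in
    counterphase (|delta phi| > pi/2).

    Both fits must share the same fixed period.  The difference is wrapped
    to (-pi, pi].
    """
    if not math.isclose(fit_a.period, fit_b.period, rel_tol=1e-12):
        raise ValueError("cosinor fits have different fixed periods")
    delta = fit_b.acrophase - fit_a.acrophase
    delta = -((-delta + math.pi) % (2.0 * math.pi) - math.pi)  # wrap to (-pi, pi]
    return delta, abs(delta) > math.pi / 2.0
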