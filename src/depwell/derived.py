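"""Whole-cell parameter conversions and benchmarking arithmetic.

DEP fits yield *specific* (per-membrane-area) capacitance and conductance;
patch-clamp studies report *whole-cell* values.  The two are related through
the cell surface area, taken as that of a sphere with the optically measured
mean radius: C_whole = C_m * 4 pi r^2 (and likewise for conductance).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "WholeCellParams",
    "whole_cell_capacitance",
    "whole_cell_conductance",
    "specific_membrane_capacitance",
    "specific_membrane_conductance",
    "specific_membrane_resistance",
    "percent_change",
    "radius_stats",
    "write_comparison_table",
]


@dataclass(frozen=True)
class WholeCellParams:
    """Whole-cell capacitance (F) and conductance (S) at a given radius (m)."""

    capacitance: float
    conductance: float
    radius: float

    def __post_init__(self) -> None:
        if self.capacitance < 0 or self.conductance < 0 or self.radius < 0:
            raise ValueError("whole-cell parameters must be non-negative")


def _surface_area(radius: float) -> float:
    return 4.0 * math.pi * radius**2


def whole_cell_capacitance(mem_capacitance: float, radius: float) -> float:
    """C_whole = C_m * 4 pi r^2, in farads."""
    if mem_capacitance < 0 or radius < 0:
        raise ValueError("inputs must be non-negative")
    return mem_capacitance * _surface_area(radius)


def whole_cell_conductance(mem_conductance: float, radius: float) -> float:
    """G_whole = G_m * 4 pi r^2, in siemens."""
    if mem_conductance < 0 or radius < 0:
        raise ValueError("inputs must be non-negative")
    return mem_conductance * _surface_area(radius)


def specific_membrane_capacitance(capacitance: float, radius: float) -> float:
    """Inverse conversion: C_m (F/m^2) from whole-cell capacitance (F)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    return capacitance / _surface_area(radius)


def specific_membrane_conductance(conductance: float, radius: float) -> float:
    """Inverse conversion: G_m (S/m^2) from whole-cell conductance (S)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    return conductance / _surface_area(radius)


def specific_membrane_resistance(mem_conductance: float) -> float:
    """Specific membrane resistance in kOhm cm^2 from G_m in S/m^2.

    1/G_m is in Ohm m^2; 1 Ohm m^2 = 1e4 Ohm cm^2, reported in kOhm cm^2,
    hence the net factor of 10.
    """
    if mem_conductance < 0:
        raise ValueError("conductance must be non-negative")
    if mem_conductance == 0:
        return math.inf
    return 10.0 / mem_conductance


def percent_change(reference: float, new: float) -> float:
    """Percentage reduction from ``reference`` to ``new``.

    Positive when ``new`` is smaller (a reduction); the complement
    ``100 - percent_change(...)`` gives the retained/recovered fraction.
    """
    if reference == 0:
        raise ValueError("reference must be non-zero")
    return 100.0 * (reference - new) / reference


def radius_stats(radii) -> tuple[float, float]:
    """Sample mean and sd of optical radius measurements (needs n >= 2)."""
    r = np.asarray(radii, dtype=float)
    if r.size < 2:
        raise ValueError("need at least two radii")
    return float(r.mean()), float(r.std(ddof=1))


def write_comparison_table(rows, path) -> None:
    """Write a parameter / measured value / literature value table as TSV.

    ``rows`` is an iterable of (parameter, measured, literature) triples;
    numeric measured values are rounded to 3 significant figures for the
    report while callers retain full precision internally.
    """

    def _fmt(v):
        if isinstance(v, (int, float)) and not isinstance(v, bool):
            return f"{v:.3g}"
        return str(v)

    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["parameter", "measured", "literature"])
        for row in rows:
            writer.writerow([_fmt(v) for v in row])
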