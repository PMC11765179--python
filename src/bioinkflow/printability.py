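"""Filament and pore quality metrics for extrusion bioprinting.

An extruded filament ideally keeps the nozzle's width; spreading of the
liquid-like hydrogel is captured by the diffusion rate.  A bilayer
deposition forms pores whose shape is scored by circularity (1 for a
circle, pi/4 for a square) and printability (1 for the targeted square
pore, below 1 for circular spreading).  A simple composition descriptor
— gelatin weight over the product of alginate and TO-NFC weights —
tracks the observed ranking of filament shape fidelity.

All lengths are in mm, areas in mm²; measurements are taken as given
(image analysis is out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import pi

__all__ = [
    "FilamentMeasurement",
    "PoreMeasurement",
    "PrintabilityMetrics",
    "diffusion_rate",
    "circularity",
    "printability",
    "gelatin_ratio",
    "truncate2",
]


@dataclass(frozen=True)
class FilamentMeasurement:
    """Printed filament width vs. the nozzle it came from (mm)."""

    FW: float  # filament width
    ND: float  # nozzle diameter

    def __post_init__(self) -> None:
        if self.FW <= 0 or self.ND <= 0:
            raise ValueError("filament width and nozzle diameter must be positive")


@dataclass(frozen=True)
class PoreMeasurement:
    """Perimeter and enclosed area of a printed pore (mm, mm²)."""

    L: float  # perimeter
    Aa: float  # actual enclosed area

    def __post_init__(self) -> None:
        if self.L <= 0 or self.Aa <= 0:
            raise ValueError("perimeter and area must be positive")
        if self.L**2 < 4 * pi * self.Aa * (1 - 1e-12):
            raise ValueError(
                f"impossible geometry: L^2 = {self.L**2:g} < 4*pi*Aa = {4 * pi * self.Aa:g} "
                "(isoperimetric inequality violated)"
            )


@dataclass(frozen=True)
class PrintabilityMetrics:
    diffusion_rate: float | None = None  # percent
    circularity: float | None = None
    printability: float | None = None
    gelatin_ratio: float | None = None


def diffusion_rate(m: FilamentMeasurement) -> float:
    """Filament width relative to the nozzle diameter, percent (FW/ND x 100)."""
    return m.FW / m.ND * 100.0


def circularity(p: PoreMeasurement) -> float:
    """Pore circularity 4*pi*Aa / L², in (0, 1]; 1 for a circle, pi/4 for a square."""
    return 4.0 * pi * p.Aa / p.L**2


def printability(p: PoreMeasurement) -> float:
    """Pore printability L² / (16 Aa) = (pi/4) / circularity; 1 for a square pore."""
    return p.L**2 / (16.0 * p.Aa)


def gelatin_ratio(composition) -> float:
    """Gelatin weight over (alginate x TO-NFC weight).

    Lower values correspond to better filament size and shape fidelity.
    Accepts anything with A, G, T attributes (e.g. CompositionSpec).
    """
    denom = composition.A * composition.T
    if denom == 0:
        raise ZeroDivisionError("alginate x TO-NFC weight is zero")
    return composition.G / denom


def truncate2(value: float) -> float:
    """Truncate (not round) to two decimals, the convention used in reports."""
    import math

    return math.trunc(value * 100) / 100.0
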