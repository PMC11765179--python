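"""Synthetic flow-curve datasets for alginate–gelatin–TO-NFC bioinks.

The modeled system is a family of hybrid hydrogels mixing alginate (A),
gelatin (G) and TEMPO-oxidized nano-fibrillated cellulose (T) at a fixed
8% total solid content, measured on a rotational rheometer over shear
rates 0.1–100 1/s.  No raw sweeps are distributed with the package;
instead, flow curves are regenerated from the characterized Cross and
Herschel–Bulkley parameter sets of the eight canonical compositions,
with optional multiplicative log-normal noise emulating instrument
scatter.

Units follow the rheometer convention: viscosity in mPa·s, shear stress
in Pa, shear rate in 1/s.  The Herschel–Bulkley consistency index K is
stored in mPa·s^n and converted to Pa·s^n internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CompositionSpec",
    "CrossParams",
    "HerschelParams",
    "GridSpec",
    "FlowCurveDataset",
    "CANONICAL_SYSTEMS",
    "cross_viscosity",
    "herschel_stress",
    "generate_dataset",
    "read_dataset",
    "write_dataset",
]

#: Exact CSV header contract for flow-curve tables.
CSV_COLUMNS = [
    "composition",
    "A",
    "G",
    "T",
    "shear_rate",
    "viscosity_mPas",
    "shear_stress_Pa",
]

TOTAL_SOLIDS = 8.0  # weight percent, fixed across the canonical design

SHEAR_RATE_MIN = 0.1  # 1/s, instrument sweep lower bound
SHEAR_RATE_MAX = 100.0  # 1/s, instrument sweep upper bound


class InvalidParameterError(ValueError):
    """A rheological parameter violates its physical constraint."""


class DatasetFormatError(ValueError):
    """A flow-curve CSV violates the dataset contract."""


@dataclass(frozen=True)
class CompositionSpec:
    """One bioink formulation: weight percents of the three solids."""

    label: str
    A: float  # alginate wt%
    G: float  # gelatin wt%
    T: float  # TO-NFC wt%

    def __post_init__(self) -> None:
        if min(self.A, self.G, self.T) <= 0:
            raise InvalidParameterError(
                f"{self.label}: component weights must be positive"
            )

    @property
    def total_solids(self) -> float:
        return self.A + self.G + self.T


@dataclass(frozen=True)
class CrossParams:
    """Cross shear-thinning model parameters.

    eta = eta_inf + (eta_0 - eta_inf) / (1 + (t * gamma_dot)**m)

    eta_inf, eta_0 in mPa·s; t in s; m dimensionless.
    """

    eta_inf: float
    eta_0: float
    t: float
    m: float

    def __post_init__(self) -> None:
        if not (self.eta_0 > self.eta_inf > 0):
            raise InvalidParameterError(
                f"require eta_0 > eta_inf > 0, got {self.eta_0}, {self.eta_inf}"
            )
        if self.t <= 0:
            raise InvalidParameterError(f"time constant t must be > 0, got {self.t}")
        if not (0 < self.m < 2):
            raise InvalidParameterError(f"transition factor m must be in (0, 2), got {self.m}")


@dataclass(frozen=True)
class HerschelParams:
    """Herschel–Bulkley yield-stress fluid parameters.

    tau = tau_0 + K * gamma_dot**n

    tau_0 in Pa; K in mPa·s^n (converted to Pa·s^n in herschel_stress);
    n dimensionless, < 1 for shear-thinning materials.
    """

    tau_0: float
    K: float
    n: float

    def __post_init__(self) -> None:
        if self.tau_0 < 0:
            raise InvalidParameterError(f"yield stress must be >= 0, got {self.tau_0}")
        if self.K <= 0:
            raise InvalidParameterError(f"consistency index must be > 0, got {self.K}")
        if not (0 < self.n <= 1):
            raise InvalidParameterError(f"flow index must be in (0, 1], got {self.n}")


@dataclass(frozen=True)
class GridSpec:
    """Log-spaced shear-rate grid inside the instrument sweep range."""

    min: float = SHEAR_RATE_MIN
    max: float = SHEAR_RATE_MAX
    n: int = 21
    spacing: str = "log"

    def __post_init__(self) -> None:
        if not (SHEAR_RATE_MIN <= self.min < self.max <= SHEAR_RATE_MAX):
            raise ValueError(
                f"grid [{self.min}, {self.max}] outside instrument range "
                f"[{SHEAR_RATE_MIN}, {SHEAR_RATE_MAX}]"
            )
        if self.n < 2:
            raise ValueError("grid needs at least 2 points")
        if self.spacing not in ("log", "linear"):
            raise ValueError(f"unknown spacing {self.spacing!r}")

    def points(self) -> np.ndarray:
        if self.spacing == "log":
            return np.geomspace(self.min, self.max, self.n)
        return np.linspace(self.min, self.max, self.n)

    def to_dict(self) -> dict:
        return {"min": self.min, "max": self.max, "n": self.n, "spacing": self.spacing}


@dataclass
class FlowCurveDataset:
    """Long-format flow-curve table plus generation metadata.

    ``frame`` has exactly the columns of :data:`CSV_COLUMNS`; one row per
    (composition, shear rate) pair.
    """

    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def compositions(self) -> list[str]:
        return list(dict.fromkeys(self.frame["composition"]))

    def features_targets(self) -> tuple[np.ndarray, np.ndarray]:
        """(gamma_dot, A, G, T) design matrix and ln-viscosity targets."""
        from .surrogates import log_target  # local import avoids a cycle

        return log_target(self)


# Characterized model parameters for the eight canonical compositions
# (flow-curve fits at 55 degC; viscosity mPa·s, K mPa·s^n, stress Pa).
CANONICAL_SYSTEMS: list[tuple[CompositionSpec, CrossParams, HerschelParams]] = [
    (CompositionSpec("A5G2T1", 5.0, 2.0, 1.0),
     CrossParams(6191, 4_182_705, 8.05, 0.83), HerschelParams(255.89, 582.6, 0.22)),
    (CompositionSpec("A4G3T1", 4.0, 3.0, 1.0),
     CrossParams(6908, 3_476_364, 10.41, 0.76), HerschelParams(200.51, 570.86, 0.27)),
    (CompositionSpec("A3G4T1", 3.0, 4.0, 1.0),
     CrossParams(1422, 2_306_424, 17.52, 0.71), HerschelParams(70.04, 298.76, 0.28)),
    (CompositionSpec("A2G5T1", 2.0, 5.0, 1.0),
     CrossParams(966, 1_956_326, 27.9, 0.63), HerschelParams(51.62, 253.21, 0.18)),
    (CompositionSpec("A5.25G2.25T0.5", 5.25, 2.25, 0.5),
     CrossParams(9157, 2_497_101, 7.06, 0.75), HerschelParams(159.78, 442.08, 0.26)),
    (CompositionSpec("A4.25G3.25T0.5", 4.25, 3.25, 0.5),
     CrossParams(2784, 606_959, 3.15, 0.67), HerschelParams(69.54, 239.52, 0.35)),
    (CompositionSpec("A3.25G4.25T0.5", 3.25, 4.25, 0.5),
     CrossParams(1298, 693_471, 5.21, 0.66), HerschelParams(77.81, 228.12, 0.32)),
    (CompositionSpec("A2.25G5.25T0.5", 2.25, 5.25, 0.5),
     CrossParams(1460, 939_531, 12.79, 0.68), HerschelParams(64.68, 171.27, 0.26)),
]


def cross_viscosity(params: CrossParams, shear_rate) -> np.ndarray | float:
    """Cross-model apparent viscosity (mPa·s) at the given shear rate(s).

    Strictly decreasing in shear rate for valid parameters; returns the
    zero-shear plateau eta_0 at shear_rate = 0 and tends to eta_inf as
    shear_rate grows.
    """
    gd = np.asarray(shear_rate, dtype=float)
    if np.any(gd < 0):
        raise ValueError("shear rate must be non-negative")
    eta = params.eta_inf + (params.eta_0 - params.eta_inf) / (1.0 + (params.t * gd) ** params.m)
    return float(eta) if np.isscalar(shear_rate) else eta


def herschel_stress(params: HerschelParams, shear_rate) -> np.ndarray | float:
    """Herschel–Bulkley shear stress (Pa) at the given shear rate(s).

    K is stored in mPa·s^n and converted to Pa·s^n (x 1e-3) here.
    """
    gd = np.asarray(shear_rate, dtype=float)
    if np.any(gd < 0):
        raise ValueError("shear rate must be non-negative")
    tau = params.tau_0 + (params.K * 1e-3) * gd ** params.n
    return float(tau) if np.isscalar(shear_rate) else tau


def generate_dataset(
    systems: Sequence[tuple[CompositionSpec, CrossParams, HerschelParams]] | None = None,
    grid: GridSpec | None = None,
    noise_sigma: float = 0.05,
    seed: int = 0,
) -> FlowCurveDataset:
    """Generate a flow-curve dataset from parametric ground truth.

    For each composition and grid point the viscosity is the Cross-model
    value times exp(eps) and the stress the Herschel–Bulkley value times
    exp(eps'), with eps, eps' drawn independently from Normal(0,
    noise_sigma^2).  noise_sigma = 0 reproduces the models exactly.

    Parameters
    ----------
    systems
        (composition, Cross, Herschel) triples; defaults to the eight
        canonical compositions.
    grid
        Shear-rate grid; defaults to 21 log-spaced points, 0.1–100 1/s.
    noise_sigma
        Standard deviation of the log-space noise (dimensionless).
    seed
        Seed for the noise stream; recorded in metadata.
    """
    if systems is None:
        systems = CANONICAL_SYSTEMS
    if len(systems) == 0:
        raise ValueError("at least one composition is required")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    grid = grid or GridSpec()

    labels = [c.label for c, _, _ in systems]
    if len(set(labels)) != len(labels):
        raise ValueError("composition labels must be unique")

    rng = np.random.default_rng(seed)
    gd = grid.points()
    rows = []
    for comp, cross, herschel in systems:
        eta = cross_viscosity(cross, gd)
        tau = herschel_stress(herschel, gd)
        if noise_sigma > 0:
            eta = eta * np.exp(rng.normal(0.0, noise_sigma, size=gd.size))
            tau = tau * np.exp(rng.normal(0.0, noise_sigma, size=gd.size))
        for g, e, s in zip(gd, eta, tau):
            rows.append((comp.label, comp.A, comp.G, comp.T, g, e, s))

    frame = pd.DataFrame(rows, columns=CSV_COLUMNS)
    metadata = {"seed": seed, "noise_sigma": noise_sigma, "grid": grid.to_dict()}
    return FlowCurveDataset(frame, metadata)


def write_dataset(dataset: FlowCurveDataset, path: str | Path) -> None:
    """Write the dataset CSV plus a JSON metadata sidecar (``<path>.meta.json``)."""
    path = Path(path)
    dataset.frame.to_csv(path, index=False)
    if dataset.metadata:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(dataset.metadata, indent=2) + "\n")


def read_dataset(path: str | Path) -> FlowCurveDataset:
    """Read a flow-curve CSV, validating the dataset contract.

    Columns are matched by name (any order).  Missing columns, non-numeric
    cells and duplicate (composition, shear_rate) pairs raise
    :class:`DatasetFormatError` naming the offending column or row.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise DatasetFormatError(f"{path}: missing column(s) {missing}")
    frame = frame[CSV_COLUMNS]
    for col in CSV_COLUMNS[1:]:
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[numeric.isna() & frame[col].notna()]
        if frame[col].isna().any():
            bad = bad.union(frame.index[frame[col].isna()])
        if len(bad):
            raise DatasetFormatError(
                f"{path}: non-numeric value in column {col!r} at row(s) {list(bad[:5])}"
            )
        frame[col] = numeric
    dup = frame.duplicated(subset=["composition", "shear_rate"])
    if dup.any():
        raise DatasetFormatError(
            f"{path}: duplicate (composition, shear_rate) at row(s) "
            f"{list(frame.index[dup][:5])}"
        )
    metadata = {}
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        metadata = json.loads(sidecar.read_text())
    return FlowCurveDataset(frame.reset_index(drop=True), metadata)
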