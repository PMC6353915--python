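"""Collagen QC arithmetic and single-date radiocarbon calibration.

Quality screening of dated material uses the atomic C:N ratio (acceptable
2.9-3.5 for bulk collagen, ~5.0 for purified hydroxyproline, whose formula
C5H9NO3 fixes the theoretical value) and the percent yield of the extraction.

Calibration maps a conventional radiocarbon age ``age ± sigma`` (years BP,
Libby convention) through a tabulated calibration curve to a posterior over
calendar age on a 1-year grid, assuming independent Gaussian errors for the
measurement and the curve and a flat calendar-age prior:

    mass(theta)  ∝  exp( -(age - mu(theta))^2 / 2 (sigma^2 + tau(theta)^2) )

with the curve mean ``mu`` and error ``tau`` linearly interpolated. Reported
ranges are highest-posterior-density (HPD) sets at a requested probability,
by default 0.954 (the two-sigma convention of common calibration software).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

#: Libby mean life in years; F14C = exp(-age / LIBBY_MEAN_LIFE).
LIBBY_MEAN_LIFE = 8033.0

#: Atomic masses used for C:N from mass percentages.
MASS_C = 12.011
MASS_N = 14.007


@dataclass
class RadiocarbonMeasurement:
    """A conventional radiocarbon determination in years BP."""

    age: float
    sigma: float
    lab_code: str = ""

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")


@dataclass
class CalibrationCurve:
    """Tabulated calibration curve: calendar age, 14C age, 1-sigma error."""

    theta: list[float] | np.ndarray
    mu_curve: list[float] | np.ndarray
    tau_curve: list[float] | np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.mu_curve = np.asarray(self.mu_curve, dtype=float)
        self.tau_curve = np.asarray(self.tau_curve, dtype=float)
        if not (len(self.theta) == len(self.mu_curve) == len(self.tau_curve)):
            raise ValueError("curve arrays must have equal length")
        if len(self.theta) < 2:
            raise ValueError("curve needs at least two rows")
        if not np.all(np.diff(self.theta) > 0):
            raise ValueError("calendar ages must be strictly increasing")

    def __len__(self) -> int:
        return len(self.theta)


@dataclass
class CalibratedDate:
    """Posterior over calendar age with HPD ranges.

    ``hpd`` holds ``(old_bound, young_bound, mass)`` tuples with bounds in
    cal BP (old >= young), rounded outward to 10 years as calibration
    software conventionally reports.
    """

    grid: np.ndarray
    density: np.ndarray
    hpd: list[tuple[float, float, float]]
    p: float
    measurement: RadiocarbonMeasurement | None = None


# ---------------------------------------------------------------------------
# QC arithmetic

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a simple molecular formula (element symbols + counts)."""
    if not formula or not re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", formula):
        raise ValueError(f"cannot parse molecular formula {formula!r}")
    counts: dict[str, int] = {}
    for symbol, number in _FORMULA_TOKEN.findall(formula):
        if symbol:
            counts[symbol] = counts.get(symbol, 0) + (int(number) if number else 1)
    return counts


def atomic_cn_from_formula(formula: str) -> float:
    """Theoretical atomic C:N ratio of a compound, e.g. 5.0 for C5H9NO3."""
    counts = parse_formula(formula)
    if "N" not in counts:
        raise ValueError(f"formula {formula!r} contains no nitrogen")
    if "C" not in counts:
        raise ValueError(f"formula {formula!r} contains no carbon")
    return counts["C"] / counts["N"]


def atomic_cn_from_percent(pC: float, pN: float) -> float:
    """Atomic C:N from mass percentages of carbon and nitrogen."""
    if pC <= 0 or pN <= 0:
        raise ValueError("mass percentages must be positive")
    return (pC / MASS_C) / (pN / MASS_N)


def percent_yield(extract_mg: float, input_mg: float) -> float:
    """Extraction yield as a percentage of starting mass, to 1 decimal."""
    if input_mg <= 0:
        raise ValueError("input mass must be positive")
    if extract_mg < 0:
        raise ValueError("extract mass must be non-negative")
    return round(100.0 * extract_mg / input_mg, 1)


def f14c(age_bp: float) -> float:
    """Fraction modern corresponding to a conventional radiocarbon age."""
    return float(np.exp(-np.asarray(age_bp, dtype=float) / LIBBY_MEAN_LIFE))


# ---------------------------------------------------------------------------
# HPD selection


def hpd_ranges(
    grid: np.ndarray,
    density: np.ndarray,
    p: float,
) -> list[tuple[float, float, float]]:
    """Highest-density subset of grid points with total mass >= p.

    Points are admitted in decreasing density order (ties broken toward
    older, i.e. larger, ages) until the accumulated mass reaches ``p``;
    the minimal such selection is returned merged into contiguous ranges
    ``(old_bound, young_bound, mass)``.
    """
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    grid = np.asarray(grid, dtype=float)
    density = np.asarray(density, dtype=float)
    if grid.shape != density.shape:
        raise ValueError("grid and density must have the same shape")
    # sort by density descending, older ages first among ties
    order = np.lexsort((-grid, -density))
    cum = np.cumsum(density[order])
    # smallest prefix reaching p (tolerate float round-off at the boundary)
    n_keep = int(np.searchsorted(cum, p - 1e-12)) + 1
    n_keep = min(n_keep, len(grid))
    selected = np.zeros(len(grid), dtype=bool)
    selected[order[:n_keep]] = True

    ranges: list[tuple[float, float, float]] = []
    i = 0
    while i < len(grid):
        if selected[i]:
            j = i
            while j + 1 < len(grid) and selected[j + 1]:
                j += 1
            mass = float(density[i : j + 1].sum())
            old, young = float(max(grid[i], grid[j])), float(min(grid[i], grid[j]))
            ranges.append((old, young, mass))
            i = j + 1
        else:
            i += 1
    # report oldest range first
    ranges.sort(key=lambda r: -r[0])
    return ranges


# ---------------------------------------------------------------------------
# Calibration


def calibrate(
    m: RadiocarbonMeasurement,
    curve: CalibrationCurve,
    p: float = 0.954,
    round_to: int = 10,
) -> CalibratedDate:
    """Calibrate a radiocarbon measurement against a curve.

    The posterior is evaluated on a 1-year calendar grid spanning the curve
    support; HPD bounds are rounded outward to ``round_to`` years. A warning
    is emitted when non-negligible posterior mass sits at the curve edge
    (truncated density).
    """
    grid = np.arange(np.ceil(curve.theta[0]), np.floor(curve.theta[-1]) + 1.0)
    mu = np.interp(grid, curve.theta, curve.mu_curve)
    tau = np.interp(grid, curve.theta, curve.tau_curve)
    var = m.sigma**2 + tau**2
    log_mass = -((m.age - mu) ** 2) / (2.0 * var)
    log_mass -= log_mass.max()
    mass = np.exp(log_mass)
    total = mass.sum()
    if total <= 0:
        raise ValueError("calibration produced zero posterior mass")
    density = mass / total
    edge = max(density[0], density[-1])
    if edge > 1e-6:
        warnings.warn(
            f"posterior mass truncated at calibration-curve edge "
            f"(edge density {edge:.2e})",
            RuntimeWarning,
            stacklevel=2,
        )
    raw = hpd_ranges(grid, density, p)
    rounded = []
    for old, young, massr in raw:
        old_r = float(np.ceil(old / round_to) * round_to) if round_to else old
        young_r = float(np.floor(young / round_to) * round_to) if round_to else young
        rounded.append((old_r, young_r, massr))
    return CalibratedDate(grid=grid, density=density, hpd=rounded, p=p, measurement=m)
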