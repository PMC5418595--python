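"""Assay arithmetic: growth inhibition, LCMS calibration, yields.

Growth inhibition is 100 × (1 − sample OD600 fold-change / control OD600
fold-change).  Calibration fits an ordinary least-squares line over the
detected linear range of (concentration, counts) standards; quantified
concentrations carry LOD/LOQ flags from signal-to-noise thresholds of 3:1 and
10:1.  All concentrations are normalised internally to pg ml⁻¹.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np


class UnitError(ValueError):
    pass


# mass-per-millilitre prefixes, normalised to pg/ml
_UNIT_FACTORS = {"pg": 1.0, "ng": 1e3, "ug": 1e6, "mg": 1e9, "g": 1e12}

_UNIT_RE = re.compile(
    r"^\s*([pnum]?g)\s*(?:/\s*ml|[ .]?ml(?:\^?-1|\^?−1)?)\s*$", re.IGNORECASE
)


def unit_factor(unit: str) -> float:
    """pg ml⁻¹ per one *unit* (accepts 'ng/ml', 'ng ml-1', 'µg ml^−1', ...)."""
    cleaned = unit.replace("µ", "u").replace("μ", "u").replace("−", "-")
    m = _UNIT_RE.match(cleaned)
    if not m:
        raise UnitError(f"unrecognised concentration unit {unit!r}")
    return _UNIT_FACTORS[m.group(1).lower()]


def to_pg_per_ml(value: float, unit: str) -> float:
    return value * unit_factor(unit)


def parse_quantity(text: str) -> float:
    """Parse '3 ng/ml'-style strings to pg ml⁻¹."""
    m = re.match(r"^\s*([0-9.eE+-]+)\s*(.+)$", text)
    if not m:
        raise UnitError(f"cannot parse quantity {text!r}")
    return to_pg_per_ml(float(m.group(1)), m.group(2))


@dataclass(frozen=True)
class PlateReading:
    """One well's OD600 readings at time zero and after overnight growth."""

    well: str
    strain: str
    od600_t0: float
    od600_t18: float
    role: str = "sample"  # sample | control

    def __post_init__(self) -> None:
        if self.od600_t0 <= 0 or self.od600_t18 <= 0:
            raise ValueError(
                f"well {self.well!r}: OD600 values must be positive "
                "(fold-change requires a nonzero baseline)"
            )
        if self.role not in ("sample", "control"):
            raise ValueError(f"well {self.well!r}: unknown role {self.role!r}")

    @property
    def fold_change_od(self) -> float:
        return self.od600_t18 / self.od600_t0


@dataclass(frozen=True)
class InhibitionResult:
    percent: float
    growth_promotion: bool  # negative inhibition, reported as computed


def growth_inhibition(sample: PlateReading, control: PlateReading) -> InhibitionResult:
    """Percent growth inhibition of *sample* relative to *control* media."""
    ratio = sample.fold_change_od / control.fold_change_od
    percent = 100.0 * (1.0 - ratio)
    return InhibitionResult(percent=percent, growth_promotion=percent < 0)


@dataclass
class CalibrationCurve:
    """OLS line over the linear range of an LCMS standard series."""

    analyte: str
    points: list[tuple[float, float]]  # (concentration pg/ml, counts), sorted
    linear_range: tuple[int, int]  # half-open index span of points used
    slope: float
    intercept: float
    lod_counts: float | None = None  # 3:1 signal-to-noise threshold
    loq_counts: float | None = None  # 10:1 signal-to-noise threshold

    def __post_init__(self) -> None:
        i0, i1 = self.linear_range
        if i1 - i0 < 2:
            raise ValueError("calibration needs >= 2 points in the linear range")
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")
        if any(c <= 0 for c, _ in self.points):
            raise ValueError("standard concentrations must be strictly positive")


#: the default standard series (pg/ml): 10 ng, 100 ng, 10 µg, 100 µg per ml
DEFAULT_STANDARDS_PG_ML = (1e4, 1e5, 1e7, 1e8)


def fit_calibration(
    points: Sequence[tuple[float, float]],
    *,
    analyte: str = "analyte",
    slope_tol: float = 0.1,
    noise: float | None = None,
) -> CalibrationCurve:
    """Fit the line of best fit over the detected linear range.

    The linear range is the longest contiguous run of standards whose
    consecutive log-log slopes deviate from 1 by at most ``slope_tol``
    (saturated standards drop out); the fit itself is OLS in linear space.
    """
    if len(points) < 2:
        raise ValueError("need at least two standards")
    pts = sorted((float(c), float(y)) for c, y in points)
    if any(c <= 0 for c, _ in pts):
        raise ValueError("standard concentrations must be strictly positive")
    if any(y < 0 for _, y in pts):
        raise ValueError("counts must be nonnegative")

    n = len(pts)
    ok = []  # ok[i]: slope between points i and i+1 is near 1
    for i in range(n - 1):
        (c0, y0), (c1, y1) = pts[i], pts[i + 1]
        if y0 <= 0 or y1 <= 0:
            ok.append(False)
            continue
        slope = (math.log(y1) - math.log(y0)) / (math.log(c1) - math.log(c0))
        ok.append(abs(slope - 1.0) <= slope_tol)

    best = (0, 0)  # half-open span
    i = 0
    while i < n - 1:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j < n - 1 and ok[j]:
            j += 1
        if (j + 1 - i) > (best[1] - best[0]):
            best = (i, j + 1)
        i = j
    if best[1] - best[0] < 2:
        raise ValueError("fewer than two standards in the detected linear range")

    x = np.array([c for c, _ in pts[best[0]:best[1]]])
    y = np.array([v for _, v in pts[best[0]:best[1]]])
    slope, intercept = np.polyfit(x, y, 1)
    return CalibrationCurve(
        analyte=analyte, points=pts, linear_range=best,
        slope=float(slope), intercept=float(intercept),
        lod_counts=None if noise is None else 3.0 * noise,
        loq_counts=None if noise is None else 10.0 * noise,
    )


@dataclass(frozen=True)
class QuantResult:
    concentration_pg_ml: float
    flags: tuple[str, ...] = ()

    @property
    def below_lod(self) -> bool:
        return "below_LOD" in self.flags

    @property
    def below_loq(self) -> bool:
        return "below_LOQ" in self.flags


def quantify(counts: float, curve: CalibrationCurve, noise: float | None = None) -> QuantResult:
    """Invert the calibration line; flag sub-LOD/LOQ signals.

    LOD is a 3:1 and LOQ a 10:1 signal-to-noise ratio.  Counts below the
    intercept give concentration 0 with a flag rather than an error.
    """
    flags: list[str] = []
    conc = (counts - curve.intercept) / curve.slope
    if conc < 0:
        conc = 0.0
        flags.append("below_calibration")
    if noise is not None:
        if noise <= 0:
            raise ValueError("noise must be positive")
        snr = counts / noise
        if snr < 3.0:
            flags.append("below_LOD")
        if snr < 10.0:
            flags.append("below_LOQ")
    return QuantResult(concentration_pg_ml=float(conc), flags=tuple(flags))


def fold_change(yield_a, yield_b) -> float:
    """Ratio of two yields with unit normalisation.

    Each argument is either '<value> <unit>' (e.g. ``"3 ng/ml"``), a
    ``(value, unit)`` pair, or a plain number already in pg ml⁻¹.
    """
    a = _as_pg_ml(yield_a)
    b = _as_pg_ml(yield_b)
    if a <= 0 or b <= 0:
        raise ValueError("yields must be positive")
    return a / b


def _as_pg_ml(value) -> float:
    if isinstance(value, str):
        return parse_quantity(value)
    if isinstance(value, (tuple, list)) and len(value) == 2:
        return to_pg_per_ml(float(value[0]), str(value[1]))
    return float(value)
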