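"""Reaction-board statics: whole-system CoM from three support readings.

A rigid board rests on three non-collinear support points; a precision
scale reads the load at each point in turn.  The system CoM is the
reading-weighted mean of the support positions

    CoM = (P1·m1 + P2·m2 + P3·m3) / (m1 + m2 + m3)

and the total supported mass is the sum of the readings.  Readings are
ingested in grams (the instrument's native unit, 0.1 g resolution) and
stored in kg; positions are in cm, so downstream moments come out in
kg·cm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import DegenerateGeometryError, EmptyLoadError
from .geometry import PlanarPoint, as_xy

#: Minimum support-triangle area (cm^2) below which geometry is degenerate.
MIN_TRIANGLE_AREA_CM2 = 1.0

#: Stated precision of the reference scale, grams.
SCALE_PRECISION_G = 1.5

#: Default tolerance for checking the summed readings against a declared
#: total: three readings, each off by up to one precision unit.
DEFAULT_TOTAL_TOL_KG = 3 * SCALE_PRECISION_G / 1000.0


def triangle_area(p1, p2, p3) -> float:
    """Unsigned area (cm^2) of the triangle p1-p2-p3."""
    a, b, c = as_xy(p1), as_xy(p2), as_xy(p3)
    u, v = b - a, c - a
    return 0.5 * abs(u[0] * v[1] - u[1] * v[0])


@dataclass(frozen=True)
class SupportSet:
    """One atomic observation: three support positions plus their readings.

    ``points`` is a (3, 2) array of positions in cm; ``readings_kg`` a
    (3,) array of scale readings in kg.  Use :meth:`from_grams` when the
    readings come straight off the scale.
    """

    points: np.ndarray
    readings_kg: np.ndarray
    min_area_cm2: float = MIN_TRIANGLE_AREA_CM2

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float).reshape(3, 2)
        rd = np.asarray(self.readings_kg, dtype=float).reshape(3)
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "readings_kg", rd)
        if not (np.all(np.isfinite(pts)) and np.all(np.isfinite(rd))):
            raise ValueError("non-finite support positions or readings")
        if np.any(rd < 0):
            raise ValueError(f"negative scale reading: {rd}")
        area = triangle_area(*pts)
        if area < self.min_area_cm2:
            raise DegenerateGeometryError(
                f"support points are (near-)collinear: triangle area "
                f"{area:.3g} cm^2 < {self.min_area_cm2:g} cm^2"
            )

    @classmethod
    def from_grams(cls, points, readings_g, **kw) -> "SupportSet":
        return cls(points, np.asarray(readings_g, dtype=float) / 1000.0, **kw)

    @property
    def readings_g(self) -> np.ndarray:
        return self.readings_kg * 1000.0

    @property
    def total_mass_kg(self) -> float:
        return float(self.readings_kg.sum())


@dataclass(frozen=True)
class BodyState:
    """Whole-system CoM and total supported mass at one posture."""

    com: PlanarPoint
    total_mass_kg: float
    label: Optional[str] = None  # "alpha" or "beta" where relevant

    def __post_init__(self):
        object.__setattr__(self, "com", PlanarPoint.from_array(self.com))
        if not self.total_mass_kg > 0:
            raise ValueError(f"total mass must be positive, got {self.total_mass_kg}")


def compute_com(supports: SupportSet, label: Optional[str] = None) -> BodyState:
    """Whole-system CoM as the reading-weighted mean of the support points.

    With non-negative readings the result lies in the support triangle's
    convex hull; the returned total mass is exactly the sum of readings.

    Raises :class:`EmptyLoadError` when all readings are zero.
    """
    total = supports.readings_kg.sum()
    if total <= 0:
        raise EmptyLoadError("all three scale readings are zero")
    com = supports.readings_kg @ supports.points / total
    return BodyState(com=PlanarPoint.from_array(com), total_mass_kg=float(total), label=label)


@dataclass(frozen=True)
class MassCheck:
    """QC report comparing summed readings against a declared total."""

    passed: bool
    measured_total_kg: float
    declared_total_kg: float
    deviation_kg: float
    tol_kg: float


def check_total_mass(
    state: BodyState, declared_total_kg: float, tol_kg: float = DEFAULT_TOTAL_TOL_KG
) -> MassCheck:
    """Flag sessions whose summed readings stray from a declared total mass.

    Report-only: never raises on failure.  Default tolerance is three
    scale-precision units (3 x 1.5 g).
    """
    if not declared_total_kg > 0:
        raise ValueError("declared total must be positive")
    dev = state.total_mass_kg - declared_total_kg
    return MassCheck(
        passed=abs(dev) <= tol_kg,
        measured_total_kg=state.total_mass_kg,
        declared_total_kg=float(declared_total_kg),
        deviation_kg=float(dev),
        tol_kg=float(tol_kg),
    )
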