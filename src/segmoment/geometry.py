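"""Planar rotation primitives.

The estimator rests on three small pieces of 2-D geometry: the rotation
matrix R(θ), the difference operator I − R(θ) that maps the segment-CoM
lever arm to the observable whole-system CoM displacement, and the scalar
"chord gain" 2·sin(θ/2) — the factor by which that lever arm is shrunk
into the measured displacement.  The chord gain's inverse is the noise
amplification of the method, which is why angles near 0° (or 360°) are
rejected outright.

Angles are accepted in degrees everywhere (the instrument protocol reads
a protractor in degrees) and converted internally.  The positive rotation
sense is counter-clockwise in the top-down camera view; pass
``clockwise_positive=True`` to flip the convention.  The estimated moment
is a magnitude and is insensitive to this choice.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np

from .errors import SingularAngleError

#: Default guard band (degrees) around the singular angles 0 and 360.
DEFAULT_ANGLE_TOL_DEG = 1.0


class PlanarPoint(NamedTuple):
    """A 2-D position in the horizontal board plane, in cm.

    Behaves as a plain ``(x, y)`` tuple, so it interoperates with numpy
    (``np.asarray(point)``) and may be used anywhere an array-like of
    length 2 is accepted.
    """

    x: float
    y: float

    @classmethod
    def from_array(cls, a) -> "PlanarPoint":
        a = np.asarray(a, dtype=float)
        return cls(float(a[0]), float(a[1]))


def as_xy(point) -> np.ndarray:
    """Coerce a PlanarPoint / tuple / array-like to a finite float64 (2,) array."""
    a = np.asarray(point, dtype=float).reshape(2)
    if not np.all(np.isfinite(a)):
        raise ValueError(f"non-finite planar coordinates: {point!r}")
    return a


def check_angle(theta_deg: float, tol_deg: float = DEFAULT_ANGLE_TOL_DEG) -> float:
    """Validate a rotation angle for estimation use.

    Raises :class:`SingularAngleError` if θ is within ``tol_deg`` of a
    multiple of 360° (where the CoM displacement vanishes).  Returns the
    angle unchanged.  Negative angles (mirror convention) are permitted.
    """
    if not math.isfinite(theta_deg):
        raise SingularAngleError(f"non-finite rotation angle: {theta_deg!r}")
    wrapped = abs(theta_deg) % 360.0
    if min(wrapped, 360.0 - wrapped) < tol_deg:
        raise SingularAngleError(
            f"rotation angle {theta_deg:g} deg is within {tol_deg:g} deg of the "
            "singular configuration (0 or 360 deg)"
        )
    return theta_deg


def rotation_matrix(theta_deg: float, *, clockwise_positive: bool = False) -> np.ndarray:
    """R(θ) = [[cosθ, −sinθ], [sinθ, cosθ]], θ in degrees, CCW positive."""
    t = math.radians(-theta_deg if clockwise_positive else theta_deg)
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, -s], [s, c]])


def difference_operator(theta_deg: float, *, clockwise_positive: bool = False) -> np.ndarray:
    """I − R(θ).

    A scaled rotation: both singular values equal ``2·|sin(θ/2)|``, so the
    operator is singular exactly at θ ∈ {0°, 360°}.  Construction never
    raises; singularity is the solver's concern.
    """
    return np.eye(2) - rotation_matrix(theta_deg, clockwise_positive=clockwise_positive)


def chord_gain(theta_deg: float, tol_deg: float = DEFAULT_ANGLE_TOL_DEG) -> float:
    """The scalar 2·|sin(θ/2)| relating lever-arm length to CoM displacement.

    ``|(I − R(θ))·v| = chord_gain(θ)·|v|`` for every planar vector v.
    Raises :class:`SingularAngleError` inside the guard band around 0/360°.
    """
    check_angle(theta_deg, tol_deg)
    return 2.0 * abs(math.sin(math.radians(theta_deg) / 2.0))
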