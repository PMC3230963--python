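"""First-order mass-moment estimator.

The method: place the whole system (segment S1 + everything else S2,
including any static board or frame) on a reaction board, measure its CoM
in posture α, rotate only S1 by a known angle θ about a fixed in-plane
rotation center, and measure the CoM again in posture β.  Everything
static cancels in the difference, leaving

    (CoM_α − CoM_β) · M = (I − R(θ)) · CoM1_α · M1

with CoM1_α the segment CoM relative to the rotation center.  Solving the
2x2 system for v = CoM1_α · (M1 / M) and taking magnitudes gives the
segment's first-order mass moment

    M⁽¹⁾ = |CoM1_α| · M1 = |v| · M        [kg·cm]

without ever knowing the segment mass M1 or lever arm separately.  The
closed-form scalar equivalent is M⁽¹⁾ = M·|ΔCoM| / (2 sin(θ/2)).

Repeated measurement sets are aggregated into the conventional summary:
mean, sample SD, and — when a calibrated reference moment is available —
the RMS deviation from it, plus relative (percent) versions of both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import InconsistentSessionError
from .geometry import (
    DEFAULT_ANGLE_TOL_DEG,
    PlanarPoint,
    as_xy,
    check_angle,
    chord_gain,
    difference_operator,
)
from .supports import SCALE_PRECISION_G, BodyState

#: Default tolerance (kg) for the α/β total-mass agreement check: 3 sigma
#: of the difference of two three-reading totals at the instrument's
#: 1.5 g precision, i.e. 3·sqrt(6)·1.5 g ≈ 11 g.
DEFAULT_PAIR_MASS_TOL_KG = 3.0 * math.sqrt(6.0) * SCALE_PRECISION_G / 1000.0


@dataclass(frozen=True)
class MeasurementPair:
    """The estimator's input: two body states, the rotation angle, and the
    rotation center (the coordinate origin the segment was rotated about).

    CoM coordinates may be expressed in any frame; only their difference
    enters the solve, which is frame-origin independent.  The rotation
    center is used to report the solved segment-CoM bearing in the
    measurement frame.
    """

    state_alpha: BodyState
    state_beta: BodyState
    theta_deg: float
    rotation_center: PlanarPoint = PlanarPoint(0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(
            self, "rotation_center", PlanarPoint.from_array(self.rotation_center)
        )


@dataclass(frozen=True)
class MomentEstimate:
    """One estimated first-order mass moment.

    ``com1_alpha_scaled`` is the solved vector v = CoM1_α·(M1/M), relative
    to the rotation center: its direction is the segment-CoM bearing at
    state α; its magnitude times the total mass is the moment.
    """

    moment_kgcm: float
    com1_alpha_scaled: PlanarPoint
    theta_deg: float
    total_mass_kg: float


def estimate_moment(
    pair: MeasurementPair,
    *,
    angle_tol_deg: float = DEFAULT_ANGLE_TOL_DEG,
    mass_tol_kg: float = DEFAULT_PAIR_MASS_TOL_KG,
    clockwise_positive: bool = False,
) -> MomentEstimate:
    """Solve (I − R(θ)) v = CoM_α − CoM_β and return M⁽¹⁾ = |v|·M.

    The total mass M is the mean of the two states' summed readings; they
    must agree within ``mass_tol_kg`` or :class:`InconsistentSessionError`
    is raised.  θ within ``angle_tol_deg`` of 0/360° raises
    :class:`SingularAngleError`.
    """
    check_angle(pair.theta_deg, angle_tol_deg)
    m_a = pair.state_alpha.total_mass_kg
    m_b = pair.state_beta.total_mass_kg
    if abs(m_a - m_b) > mass_tol_kg:
        raise InconsistentSessionError(
            f"total supported mass disagrees between states: "
            f"alpha {m_a:.4f} kg vs beta {m_b:.4f} kg "
            f"(|diff| {abs(m_a - m_b) * 1000:.1f} g > tol {mass_tol_kg * 1000:.1f} g)"
        )
    total_mass = 0.5 * (m_a + m_b)
    origin = as_xy(pair.rotation_center)
    delta = (as_xy(pair.state_alpha.com) - origin) - (as_xy(pair.state_beta.com) - origin)
    op = difference_operator(pair.theta_deg, clockwise_positive=clockwise_positive)
    v = np.linalg.solve(op, delta)
    return MomentEstimate(
        moment_kgcm=float(np.linalg.norm(v) * total_mass),
        com1_alpha_scaled=PlanarPoint.from_array(v),
        theta_deg=pair.theta_deg,
        total_mass_kg=total_mass,
    )


def estimate_moment_scalar(
    delta_com_norm_cm: float,
    theta_deg: float,
    total_mass_kg: float,
    *,
    angle_tol_deg: float = DEFAULT_ANGLE_TOL_DEG,
) -> float:
    """Closed-form M⁽¹⁾ = M·|ΔCoM| / (2 sin(θ/2)), equivalent to the
    matrix solve because I − R(θ) is a scaled rotation."""
    return total_mass_kg * delta_com_norm_cm / chord_gain(theta_deg, angle_tol_deg)


@dataclass(frozen=True)
class SessionSummary:
    """Aggregate of repeated moment measurements.

    ``sd_kgcm`` is the sample standard deviation (n−1 denominator), absent
    for n < 2.  RMS fields are present only when a calibrated reference
    moment was supplied; relative figures are percentages against the
    calibrated value when available, else against the mean.
    """

    n: int
    mean_kgcm: float
    sd_kgcm: Optional[float]
    calibrated_kgcm: Optional[float]
    rms_vs_calibrated_kgcm: Optional[float]
    relative_sd_pct: Optional[float]
    relative_rms_pct: Optional[float]

    @property
    def reference_kgcm(self) -> float:
        return self.calibrated_kgcm if self.calibrated_kgcm is not None else self.mean_kgcm


def summarize_session(
    estimates: Sequence[MomentEstimate | float],
    calibrated_kgcm: Optional[float] = None,
) -> SessionSummary:
    """Summarize repeated measurements of the same moment.

    Accepts :class:`MomentEstimate` objects or bare kg·cm values.  The RMS
    deviation is computed against the calibrated moment when given; that
    same calibrated value is the denominator for the relative figures.
    """
    values = np.array(
        [e.moment_kgcm if isinstance(e, MomentEstimate) else float(e) for e in estimates],
        dtype=float,
    )
    if values.size == 0:
        raise ValueError("summarize_session requires at least one estimate")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size >= 2 else None
    reference = calibrated_kgcm if calibrated_kgcm is not None else mean
    rms = (
        float(np.sqrt(np.mean((values - calibrated_kgcm) ** 2)))
        if calibrated_kgcm is not None
        else None
    )
    return SessionSummary(
        n=int(values.size),
        mean_kgcm=mean,
        sd_kgcm=sd,
        calibrated_kgcm=None if calibrated_kgcm is None else float(calibrated_kgcm),
        rms_vs_calibrated_kgcm=rms,
        relative_sd_pct=None if sd is None else 100.0 * sd / reference,
        relative_rms_pct=None if rms is None else 100.0 * rms / calibrated_kgcm,
    )
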