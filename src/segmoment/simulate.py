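"""Forward measurement model and synthetic-session generator.

Ground truth is a rigid configuration: one segment that rotates in the
horizontal plane about a fixed center (the coordinate origin), a static
"rest of body" mass, and a static carrier (the board or frame), all
resting on a board supported at three non-collinear points.  The forward
model rotates the segment, mass-weights the CoMs, solves the statics for
the three support loads (barycentric coordinates times the total mass),
and optionally corrupts the records with measurement noise:

* Gaussian scale noise per reading, then quantization to the scale's
  display resolution (defaults: the reference instrument's 1.5 g
  precision and 0.1 g resolution);
* Gaussian error on the recorded rotation angle (manual protractor
  reading of overlapped photographs, default sigma 0.5 degrees);
* a per-set common-mode Gaussian error on the recorded support
  positions (straightedge digitization of the same photographs; the
  supports themselves do not move between the two states, so the error
  is shared by the alpha and beta records of a set, default sigma
  0.2 cm);
* an optional posture-drift term emulating single-scale sequential
  weighing: the true system CoM is perturbed independently for each of
  the three readings (default off).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .errors import TippingError
from .geometry import PlanarPoint, as_xy, check_angle, rotation_matrix
from .supports import MIN_TRIANGLE_AREA_CM2, BodyState, SupportSet, triangle_area

#: Barycentric weights more negative than this raise a tipping error;
#: tiny negatives from rounding at a vertex/edge are clamped to zero.
_TIP_TOL = 1e-9


@dataclass(frozen=True)
class RigidSegment:
    """The rotated segment: mass M1 (kg) and its CoM in the segment frame,
    whose origin is the rotation center (cm)."""

    mass_kg: float
    com_local: PlanarPoint

    def __post_init__(self):
        object.__setattr__(self, "com_local", PlanarPoint.from_array(self.com_local))
        if not self.mass_kg > 0:
            raise ValueError("segment mass must be positive")

    @property
    def moment_kgcm(self) -> float:
        """True first-order mass moment M1·|CoM1| about the rotation center."""
        return self.mass_kg * float(np.linalg.norm(as_xy(self.com_local)))


@dataclass(frozen=True)
class RigidBodyModel:
    """Segment + static remainder + static carrier on a support triangle.

    All positions are in the lab frame whose origin is the rotation
    center.  ``carrier`` is the board or frame the subject lies on: its
    load registers on the scales but, being static, cancels exactly in
    the CoM difference — the estimator never needs to know it.
    """

    segment: RigidSegment
    rest_mass_kg: float
    rest_com: PlanarPoint
    carrier_mass_kg: float
    carrier_com: PlanarPoint
    support_triangle: np.ndarray  # (3, 2) cm

    def __post_init__(self):
        object.__setattr__(self, "rest_com", PlanarPoint.from_array(self.rest_com))
        object.__setattr__(self, "carrier_com", PlanarPoint.from_array(self.carrier_com))
        tri = np.asarray(self.support_triangle, dtype=float).reshape(3, 2)
        object.__setattr__(self, "support_triangle", tri)
        if self.rest_mass_kg < 0 or self.carrier_mass_kg < 0:
            raise ValueError("rest and carrier masses must be non-negative")
        if triangle_area(*tri) < MIN_TRIANGLE_AREA_CM2:
            raise ValueError("degenerate support triangle")

    @property
    def total_mass_kg(self) -> float:
        return self.segment.mass_kg + self.rest_mass_kg + self.carrier_mass_kg

    @property
    def true_moment_kgcm(self) -> float:
        return self.segment.moment_kgcm


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise configuration; all sigmas >= 0, quantization is
    applied after the Gaussian scale noise."""

    scale_sigma_g: float = 1.5
    scale_quantum_g: float = 0.1
    angle_sigma_deg: float = 0.5
    position_sigma_cm: float = 0.2
    drift_sigma_cm: float = 0.0

    def __post_init__(self):
        for name in (
            "scale_sigma_g",
            "scale_quantum_g",
            "angle_sigma_deg",
            "position_sigma_cm",
            "drift_sigma_cm",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def none(cls) -> "NoiseModel":
        """Exact measurements: no noise, no quantization."""
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)

    def only(self, source: str) -> "NoiseModel":
        """A copy with every source but ``source`` switched off.

        ``source`` is one of 'scale' (keeps quantization too), 'angle',
        'position', 'drift'.
        """
        base = {
            "scale_sigma_g": 0.0,
            "scale_quantum_g": 0.0,
            "angle_sigma_deg": 0.0,
            "position_sigma_cm": 0.0,
            "drift_sigma_cm": 0.0,
        }
        keep = {
            "scale": ("scale_sigma_g", "scale_quantum_g"),
            "angle": ("angle_sigma_deg",),
            "position": ("position_sigma_cm",),
            "drift": ("drift_sigma_cm",),
        }
        if source not in keep:
            raise ValueError(f"unknown noise source {source!r}")
        for name in keep[source]:
            base[name] = getattr(self, name)
        return NoiseModel(**base)


def system_com(model: RigidBodyModel, theta_deg: float) -> BodyState:
    """Whole-system CoM and total mass with the segment rotated by θ."""
    seg_com = rotation_matrix(theta_deg) @ as_xy(model.segment.com_local)
    weighted = (
        model.segment.mass_kg * seg_com
        + model.rest_mass_kg * as_xy(model.rest_com)
        + model.carrier_mass_kg * as_xy(model.carrier_com)
    )
    total = model.total_mass_kg
    return BodyState(com=PlanarPoint.from_array(weighted / total), total_mass_kg=total)


def forward_loads(com, total_mass_kg: float, triangle) -> SupportSet:
    """Exact support loads: barycentric coordinates of the CoM times the
    total mass.  Raises :class:`TippingError` when the CoM falls outside
    the triangle (a support load would be negative)."""
    tri = np.asarray(triangle, dtype=float).reshape(3, 2)
    c = as_xy(com)
    a = np.vstack([np.ones(3), tri.T])  # rows: sum, x-moment, y-moment
    w = np.linalg.solve(a, np.array([1.0, c[0], c[1]]))
    if np.any(w < -_TIP_TOL):
        raise TippingError(
            f"system CoM ({c[0]:.2f}, {c[1]:.2f}) cm lies outside the support "
            f"triangle: barycentric weights {np.round(w, 6)}"
        )
    return SupportSet(points=tri, readings_kg=np.clip(w, 0.0, None) * total_mass_kg)


@dataclass(frozen=True)
class SimulatedRecord:
    """One measurement set: the recorded alpha and beta support sets, the
    recorded rotation angle, and the true angle used to generate them."""

    set_id: str
    alpha: SupportSet
    beta: SupportSet
    theta_recorded_deg: float
    theta_true_deg: float


@dataclass(frozen=True)
class SimulatedSession:
    """A batch of simulated measurement sets plus their generating truth."""

    records: List[SimulatedRecord]
    model: RigidBodyModel

    @property
    def true_moment_kgcm(self) -> float:
        return self.model.true_moment_kgcm


def _noisy_support_set(
    model: RigidBodyModel,
    theta_deg: float,
    noise: NoiseModel,
    rng: np.random.Generator,
    position_offset: np.ndarray,
) -> SupportSet:
    """Loads at posture θ with scale noise/quantization and drift applied;
    recorded positions are the true ones plus the per-set common offset."""
    tri = model.support_triangle
    state = system_com(model, theta_deg)
    if noise.drift_sigma_cm > 0:
        # sequential weighing: reading i taken at an independently drifted CoM
        readings = np.empty(3)
        for i in range(3):
            drifted = as_xy(state.com) + rng.normal(0.0, noise.drift_sigma_cm, size=2)
            readings[i] = forward_loads(drifted, state.total_mass_kg, tri).readings_kg[i]
    else:
        readings = forward_loads(state.com, state.total_mass_kg, tri).readings_kg
    grams = readings * 1000.0
    if noise.scale_sigma_g > 0:
        grams = grams + rng.normal(0.0, noise.scale_sigma_g, size=3)
    if noise.scale_quantum_g > 0:
        grams = np.round(grams / noise.scale_quantum_g) * noise.scale_quantum_g
    return SupportSet.from_grams(tri + position_offset, np.clip(grams, 0.0, None))


def simulate_session(
    model: RigidBodyModel,
    theta_list_deg: Sequence[float],
    noise: Optional[NoiseModel] = None,
    n_repeats: int = 1,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedSession:
    """Generate ``n_repeats`` measurement sets per angle in ``theta_list_deg``.

    State alpha is the reference posture θ=0; state beta has the segment
    rotated by the set's angle.  ``noise=None`` (or :meth:`NoiseModel.none`)
    yields exact records that any downstream estimator must invert to the
    true moment to machine precision.  Reproducible for a fixed ``seed``.
    """
    if noise is None:
        noise = NoiseModel.none()
    if rng is None:
        rng = np.random.default_rng(seed)
    records: List[SimulatedRecord] = []
    k = 0
    for theta in theta_list_deg:
        check_angle(theta)
        for _ in range(n_repeats):
            k += 1
            offset = (
                rng.normal(0.0, noise.position_sigma_cm, size=(3, 2))
                if noise.position_sigma_cm > 0
                else np.zeros((3, 2))
            )
            alpha = _noisy_support_set(model, 0.0, noise, rng, offset)
            beta = _noisy_support_set(model, theta, noise, rng, offset)
            theta_rec = theta + (
                rng.normal(0.0, noise.angle_sigma_deg) if noise.angle_sigma_deg > 0 else 0.0
            )
            records.append(
                SimulatedRecord(
                    set_id=f"set{k:03d}",
                    alpha=alpha,
                    beta=beta,
                    theta_recorded_deg=float(theta_rec),
                    theta_true_deg=float(theta),
                )
            )
    return SimulatedSession(records=records, model=model)
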