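"""Ready-made ground-truth configurations for the two benchmark setups.

``dummy_bar_model`` mirrors the calibration experiment: a uniform
aluminum bar (3.013 kg, 77.2 cm) pivoted at one end plays the segment, so
its CoM sits 38.6 cm from the rotation center and the true moment is
3.013 x 38.6 = 116.3018 kg·cm; a 52.066 kg block is the static remainder
and an 11.627 kg board the carrier.

``human_leg_model`` emulates the human measurement: subject 63.460 kg
(clothes included) on a 15.569 kg frame, one leg rotated by 48.8 degrees.
The subject's true leg parameters are unknown, so the synthetic leg is
10.0 kg with a 38.88 cm lever, making the true moment equal the reported
388.8 kg·cm mean; comparisons against this preset are qualitative.

Neither experiment reports the support-triangle geometry; both presets
use an equilateral triangle centered near the system CoM (circumradius
60 cm for the bench-top dummy setup, 70 cm for the human frame), which
keeps all three loads positive at every admissible rotation angle.
"""

from __future__ import annotations

import numpy as np

from .simulate import RigidBodyModel, RigidSegment

#: Rotation angle used for every set of the human-leg measurement, degrees.
HUMAN_LEG_THETA_DEG = 48.8

#: Angle span covered by the dummy-bar measurement campaign, degrees.
DUMMY_BAR_THETA_RANGE_DEG = (30.0, 180.0)

#: Number of measurement sets in the two campaigns.
DUMMY_BAR_N_SETS = 30
HUMAN_LEG_N_SETS = 15


def _equilateral(center, circumradius: float) -> np.ndarray:
    cx, cy = center
    angles = np.deg2rad([90.0, 210.0, 330.0])
    return np.column_stack(
        [cx + circumradius * np.cos(angles), cy + circumradius * np.sin(angles)]
    )


def dummy_bar_model() -> RigidBodyModel:
    """Uniform end-pivoted bar + block + board; true moment 116.3018 kg·cm."""
    bar_mass, bar_length = 3.013, 77.2
    return RigidBodyModel(
        segment=RigidSegment(mass_kg=bar_mass, com_local=(bar_length / 2.0, 0.0)),
        rest_mass_kg=52.066,
        rest_com=(26.0, 0.0),
        carrier_mass_kg=11.627,
        carrier_com=(26.0, 0.0),
        support_triangle=_equilateral((24.8, 0.9), 60.0),
    )


def human_leg_model() -> RigidBodyModel:
    """Synthetic subject + frame with a 10 kg leg tuned to a 388.8 kg·cm moment."""
    leg_mass = 10.0
    lever_cm = 388.8 / leg_mass
    return RigidBodyModel(
        segment=RigidSegment(mass_kg=leg_mass, com_local=(lever_cm, 0.0)),
        rest_mass_kg=63.460 - leg_mass,
        rest_com=(35.4, 0.0),
        carrier_mass_kg=15.569,
        carrier_com=(35.4, 0.0),
        support_triangle=_equilateral((34.0, 1.8), 70.0),
    )


PRESETS = {
    "dummy-bar": dummy_bar_model,
    "human-leg": human_leg_model,
}


def get_preset(name: str) -> RigidBodyModel:
    try:
        return PRESETS[name]()
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
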