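"""Forward model, statics inversion, and synthetic-session generation."""

import dataclasses
import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from segmoment import (
    NoiseModel,
    RigidBodyModel,
    RigidSegment,
    TippingError,
    compute_com,
    estimate_moment,
    forward_loads,
    simulate_session,
    system_com,
)
from segmoment.io import pairs_from_records

TRIANGLE = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0]])


class TestSystemCom:
    def test_segment_on_axis_is_theta_independent(self):
        model = RigidBodyModel(
            segment=RigidSegment(mass_kg=5.0, com_local=(0.0, 0.0)),
            rest_mass_kg=20.0,
            rest_com=(30.0, 10.0),
            carrier_mass_kg=0.0,
            carrier_com=(0.0, 0.0),
            support_triangle=TRIANGLE,
        )
        states = [system_com(model, t) for t in (10.0, 90.0, 270.0)]
        for s in states[1:]:
            assert tuple(s.com) == pytest.approx(tuple(states[0].com))

    def test_segment_only_model_is_pure_rotation(self):
        model = RigidBodyModel(
            segment=RigidSegment(mass_kg=2.0, com_local=(10.0, 0.0)),
            rest_mass_kg=0.0,
            rest_com=(0.0, 0.0),
            carrier_mass_kg=0.0,
            carrier_com=(0.0, 0.0),
            support_triangle=TRIANGLE,
        )
        state = system_com(model, 90.0)
        assert tuple(state.com) == pytest.approx((0.0, 10.0), abs=1e-12)

    def test_dummy_configuration_chord_displacement(self, dummy_model):
        # |CoM(0) - CoM(180)| must equal 2 sin(90 deg) x M1L / M = 2 x 116.3018 / 66.706
        a = np.asarray(system_com(dummy_model, 0.0).com)
        b = np.asarray(system_com(dummy_model, 180.0).com)
        assert np.linalg.norm(a - b) == pytest.approx(2 * 116.3018 / 66.706, rel=1e-12)


class TestForwardLoads:
    def test_centroid_gives_equal_loads(self):
        loads = forward_loads(TRIANGLE.mean(axis=0), 30.0, TRIANGLE)
        np.testing.assert_allclose(loads.readings_kg, [10.0, 10.0, 10.0], atol=1e-12)

    def test_vertex_gets_all_load(self):
        loads = forward_loads((0.0, 0.0), 30.0, TRIANGLE)
        np.testing.assert_allclose(loads.readings_kg, [30.0, 0.0, 0.0], atol=1e-12)

    def test_barycentric_example(self):
        # oracle: solving the 3x3 statics system for com (30, 50), mass 100
        loads = forward_loads((30.0, 50.0), 100.0, TRIANGLE)
        np.testing.assert_allclose(loads.readings_kg, [20.0, 30.0, 50.0], atol=1e-12)

    def test_com_outside_triangle_tips(self):
        with pytest.raises(TippingError):
            forward_loads((-5.0, 50.0), 10.0, TRIANGLE)

    @settings(derandomize=True, max_examples=200)
    @given(
        w1=st.floats(0.001, 1.0),
        w2=st.floats(0.001, 1.0),
        w3=st.floats(0.001, 1.0),
        mass=st.floats(1.0, 200.0),
    )
    def test_statics_round_trip(self, w1, w2, w3, mass):
        """compute_com(forward_loads(c, m)) recovers (c, m) for interior points."""
        w = np.array([w1, w2, w3])
        w /= w.sum()
        com = w @ TRIANGLE
        state = compute_com(forward_loads(com, mass, TRIANGLE))
        np.testing.assert_allclose(np.asarray(state.com), com, atol=1e-12 * 100)
        assert state.total_mass_kg == pytest.approx(mass, rel=1e-12)

    def test_load_conservation(self, rng):
        for _ in range(100):
            w = rng.dirichlet([1.0, 1.0, 1.0])
            loads = forward_loads(w @ TRIANGLE, 66.706, TRIANGLE)
            assert loads.total_mass_kg == pytest.approx(66.706, rel=1e-14)


class TestSimulateSession:
    def test_noiseless_inverse_crime(self, dummy_model):
        session = simulate_session(dummy_model, [48.8])
        (_, pair), = pairs_from_records(session.records)
        est = estimate_moment(pair)
        assert est.moment_kgcm == pytest.approx(session.true_moment_kgcm, rel=1e-10)

    def test_same_seed_reproduces_session(self, dummy_model, default_noise):
        def run():
            s = simulate_session(dummy_model, [30.0, 90.0], noise=default_noise, seed=7)
            return [
                (r.set_id, r.theta_recorded_deg, r.alpha.readings_g.tolist(),
                 r.beta.readings_g.tolist(), r.alpha.points.tolist())
                for r in s.records
            ]

        assert json.dumps(run()) == json.dumps(run())

    def test_different_seeds_differ(self, dummy_model, default_noise):
        a = simulate_session(dummy_model, [90.0], noise=default_noise, seed=1)
        b = simulate_session(dummy_model, [90.0], noise=default_noise, seed=2)
        assert not np.allclose(a.records[0].alpha.readings_g, b.records[0].alpha.readings_g)

    def test_readings_are_quantized(self, dummy_model):
        noise = NoiseModel(scale_sigma_g=1.5, scale_quantum_g=0.1,
                           angle_sigma_deg=0.0, position_sigma_cm=0.0)
        session = simulate_session(dummy_model, [90.0], noise=noise, seed=3)
        grams = session.records[0].alpha.readings_g
        np.testing.assert_allclose(grams, np.round(grams * 10) / 10, atol=1e-9)

    def test_position_noise_is_common_to_both_states(self, dummy_model):
        """Support digitization error is per set: alpha and beta records of a
        set must carry identical (perturbed) support coordinates."""
        noise = NoiseModel(scale_sigma_g=0.0, scale_quantum_g=0.0,
                           angle_sigma_deg=0.0, position_sigma_cm=0.5)
        session = simulate_session(dummy_model, [90.0], noise=noise, n_repeats=3, seed=4)
        for rec in session.records:
            np.testing.assert_array_equal(rec.alpha.points, rec.beta.points)
            assert not np.allclose(rec.alpha.points, dummy_model.support_triangle)

    def test_truth_moment_matches_segment(self, dummy_model):
        session = simulate_session(dummy_model, [60.0])
        assert session.true_moment_kgcm == pytest.approx(3.013 * 38.6, rel=1e-14)

    def test_tipping_configuration_raises(self):
        model = RigidBodyModel(
            segment=RigidSegment(mass_kg=40.0, com_local=(80.0, 0.0)),
            rest_mass_kg=10.0,
            rest_com=(30.0, 30.0),
            carrier_mass_kg=0.0,
            carrier_com=(0.0, 0.0),
            support_triangle=TRIANGLE,
        )
        with pytest.raises(TippingError):
            simulate_session(model, [180.0])

    def test_posture_drift_perturbs_readings(self, dummy_model):
        noise = NoiseModel(scale_sigma_g=0.0, scale_quantum_g=0.0,
                           angle_sigma_deg=0.0, position_sigma_cm=0.0,
                           drift_sigma_cm=0.5)
        noisy = simulate_session(dummy_model, [90.0], noise=noise, seed=5)
        clean = simulate_session(dummy_model, [90.0])
        assert not np.allclose(
            noisy.records[0].alpha.readings_kg, clean.records[0].alpha.readings_kg
        )


def test_noise_model_rejects_negative_sigmas():
    with pytest.raises(ValueError):
        NoiseModel(scale_sigma_g=-1.0)


def test_noise_model_single_source_selector(default_noise):
    only_angle = default_noise.only("angle")
    assert only_angle.angle_sigma_deg == default_noise.angle_sigma_deg
    assert only_angle.scale_sigma_g == 0.0
    assert only_angle.scale_quantum_g == 0.0
    assert only_angle.position_sigma_cm == 0.0
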