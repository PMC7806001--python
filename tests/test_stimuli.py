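"""Stimulus projection, sensitivity laws, and response vectors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import growsim as gs

vec3 = st.lists(st.floats(-5.0, 5.0), min_size=3, max_size=3).map(np.array)


def _unit(v):
    return v / np.linalg.norm(v)


class TestPerpendicularComponent:
    def test_orthogonal_signal_unchanged(self):
        out = gs.perpendicular_component([2.0, 0.0, 0.0], [0.0, 0.0, 1.0])
        assert np.array_equal(out, [2.0, 0.0, 0.0])

    def test_parallel_signal_vanishes(self):
        out = gs.perpendicular_component([0.0, 0.0, 3.0], [0.0, 0.0, 1.0])
        assert np.allclose(out, 0.0, atol=1e-15)

    @given(vec3, vec3)
    @settings(deadline=None, derandomize=True)
    def test_magnitude_is_sine_projection(self, signal, axis):
        if np.linalg.norm(axis) < 1e-3 or np.linalg.norm(signal) < 1e-6:
            return
        tangent = _unit(axis)
        out = gs.perpendicular_component(signal, tangent)
        # |I_perp| = |I| sin(theta), theta the angle between signal and tangent
        cos_t = signal @ tangent / np.linalg.norm(signal)
        sin_t = np.sqrt(max(0.0, 1.0 - cos_t**2))
        # atol accommodates sqrt cancellation for near-parallel pairs
        assert np.isclose(np.linalg.norm(out), np.linalg.norm(signal) * sin_t, atol=1e-6)
        assert abs(out @ tangent) < 1e-9

    @given(vec3, vec3)
    @settings(deadline=None, derandomize=True)
    def test_idempotent(self, signal, axis):
        if np.linalg.norm(axis) < 1e-3:
            return
        tangent = _unit(axis)
        once = gs.perpendicular_component(signal, tangent)
        twice = gs.perpendicular_component(once, tangent)
        assert np.allclose(once, twice, atol=1e-12)


class TestSensitivityFunction:
    def test_constant_law_ignores_intensity(self):
        sens = gs.SensitivityFunction.constant(0.3)
        assert np.all(sens(np.array([0.1, 5.0, 100.0])) == 0.3)

    def test_weber_fechner_reference_point(self):
        sens = gs.SensitivityFunction("weber_fechner", a=0.2, b=0.1, I0=2.0)
        assert np.isclose(sens(2.0), 0.2)
        assert np.isclose(sens(2.0 * np.e), 0.3)

    def test_stevens_power_law(self):
        sens = gs.SensitivityFunction("stevens", a=2.0, b=0.5)
        assert np.isclose(sens(4.0), 4.0)


class TestResponseVector:
    def test_constant_field_perpendicular_tangent(self):
        field = gs.StimulusField("constant", direction=np.array([1.0, 0.0, 0.0]))
        sens = gs.SensitivityFunction.constant(0.1)
        out = gs.response_vector(field, sens, np.zeros(3), np.array([0.0, 0.0, 1.0]))
        # raw response is antiparallel to the effective stimulus direction
        assert np.allclose(out, [-0.1, 0.0, 0.0], atol=1e-15)

    def test_tangential_signal_gives_zero(self):
        field = gs.StimulusField("constant", direction=np.array([0.0, 0.0, 1.0]))
        sens = gs.SensitivityFunction.constant(0.1)
        out = gs.response_vector(field, sens, np.zeros(3), np.array([0.0, 0.0, 1.0]))
        assert np.all(out == 0.0)

    def test_linear_stevens_reduces_to_projected_intensity(self):
        field = gs.StimulusField(
            "constant", direction=_unit(np.array([1.0, 0.0, 1.0])), magnitude0=2.0
        )
        sens = gs.SensitivityFunction.linear(1.0)
        tangent = np.array([0.0, 0.0, 1.0])
        out = gs.response_vector(field, sens, np.zeros(3), tangent)
        # |response| = I_perp = |I| sin(45 deg)
        assert np.isclose(np.linalg.norm(out), 2.0 * np.sqrt(0.5), atol=1e-12)

    def test_magnitude_bounded_by_gain(self):
        field = gs.StimulusField("constant", direction=np.array([1.0, 0.0, 0.0]))
        sens = gs.SensitivityFunction.constant(0.1)
        rng = np.random.default_rng(7)
        for _ in range(20):
            tangent = _unit(rng.normal(size=3))
            out = gs.response_vector(field, sens, np.zeros(3), tangent)
            assert np.linalg.norm(out) <= 0.1 + 1e-12

    def test_point_source_mirror_symmetry(self):
        field = gs.StimulusField("point", source_point=np.zeros(3))
        sens = gs.SensitivityFunction.constant(0.2)
        tangent = np.array([0.0, 0.0, 1.0])
        left = gs.response_vector(field, sens, np.array([-1.0, 0.0, 0.0]), tangent)
        right = gs.response_vector(field, sens, np.array([1.0, 0.0, 0.0]), tangent)
        assert np.allclose(left, -right, atol=1e-14)

    def test_degenerate_point_source_raises(self):
        field = gs.StimulusField("point", source_point=np.zeros(3))
        sens = gs.SensitivityFunction.constant(0.2)
        with pytest.raises(gs.DegenerateSourceError):
            gs.response_vector(field, sens, np.zeros(3), np.array([0.0, 0.0, 1.0]))


class TestLineDisplacement:
    def test_point_on_line_gives_zero(self):
        out = gs.line_displacement(
            np.array([0.0, 0.0, 7.0]), np.zeros(3), np.array([0.0, 0.0, 1.0])
        )
        assert np.allclose(out, 0.0, atol=1e-15)

    def test_vertical_line_projection(self):
        out = gs.line_displacement(
            np.array([2.0, 0.0, 5.0]), np.zeros(3), np.array([0.0, 0.0, 1.0])
        )
        assert np.allclose(out, [2.0, 0.0, 0.0], atol=1e-15)

    @given(vec3, vec3, vec3)
    @settings(deadline=None, derandomize=True)
    def test_orthogonal_to_line(self, position, base, axis):
        if np.linalg.norm(axis) < 1e-3:
            return
        direction = _unit(axis)
        rho = gs.line_displacement(position, base, direction)
        assert abs(rho @ direction) < 1e-9


class TestApicalBroadcast:
    def test_identity_transport_on_same_frame(self):
        frame = np.eye(3)
        resp = np.array([0.3, -0.2, 0.9])
        out = gs.apical_broadcast(resp, frame, frame)
        assert np.allclose(out, [0.3, -0.2, 0.0], atol=1e-15)  # tangential part dropped

    def test_tangential_response_broadcasts_to_zero(self):
        frame = np.eye(3)
        out = gs.apical_broadcast(np.array([0.0, 0.0, 1.0]), frame, frame)
        assert np.all(out == 0.0)

    def test_straight_organ_apical_equals_local(self):
        # on a straight organ all frames coincide, so apical and local
        # sensing must produce identical differential-growth fields
        cfg = gs.SimulationConfig(scenario="distant", n_steps=0)
        state = cfg.initial_state()
        frames, positions = gs.propagate_frames(state)
        local = gs.build_scenario(cfg)
        apical = gs.build_scenario(
            gs.SimulationConfig(scenario="distant", n_steps=0, sensing_mode="apical")
        )
        d_local = gs.differential_growth_vector(state, frames, positions, local, 0.0)
        d_apical = gs.differential_growth_vector(state, frames, positions, apical, 0.0)
        assert np.allclose(d_local[0], d_apical[0], atol=1e-14)
        assert np.allclose(d_local[1], d_apical[1], atol=1e-14)
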