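"""Growth velocity, curvature stepping, tip growth, and composition rules."""

import numpy as np
import pytest

import growsim as gs


def _straight(n=100, ds=0.01, Lgz=1.0, R=0.1):
    return gs.straight_organ(n, ds, Lgz, R)


class TestGrowthVelocity:
    def test_tip_velocity(self):
        v = gs.growth_velocity(_straight(), 0.1)
        assert np.isclose(v[-1], 1.0 * 0.1)

    def test_zero_below_growth_zone(self):
        state = _straight(n=300)
        v = gs.growth_velocity(state, 0.1)
        # segments more than Lgz from the tip do not move
        assert np.all(v[:199] == 0.0)
        assert np.all(v[200:] > 0.0)

    def test_midpoint_of_growth_zone(self):
        state = _straight(n=200)
        v = gs.growth_velocity(state, 0.1)
        mid = 200 - 1 - 50  # depth Lgz/2 from the tip
        assert np.isclose(v[mid], 1.0 * 0.1 / 2)

    def test_nondecreasing(self):
        v = gs.growth_velocity(_straight(n=250), 0.1)
        assert np.all(np.diff(v) >= 0.0)


class TestStepCurvature:
    def test_fixed_point_without_forcing(self, curved_state):
        n = curved_state.n_segments
        zero = (np.zeros(n), np.zeros(n))
        out = gs.step_curvature(curved_state, zero, np.zeros(n), 0.1, 0.1)
        assert np.array_equal(out.kappa1, curved_state.kappa1)
        assert np.array_equal(out.kappa2, curved_state.kappa2)

    def test_single_step_source_only(self):
        # straight organ, uniform Delta.m1 = 0.1, no convection:
        # kappa1 <- dt * (Edot/R) * 0.1 = 0.1 * 1.0 * 0.1 = 0.01
        state = _straight()
        n = state.n_segments
        delta = (np.full(n, 0.1), np.zeros(n))
        out = gs.step_curvature(state, delta, np.zeros(n), 0.1, 0.1)
        assert np.allclose(out.kappa1[1:], 0.01, atol=1e-15)
        assert out.kappa1[0] == 0.0  # clamped base
        assert np.all(out.kappa2 == 0.0)

    def test_advection_matches_reference_upwind(self):
        # independent scalar-advection oracle written with explicit loops
        state = _straight(n=150)
        n = state.n_segments
        s = np.arange(n) * state.ds
        kappa1 = np.where(s > 0.5, (s - 0.5) * 2.0, 0.0)  # linear ramp in the gz
        kappa1[0] = 0.0
        state = gs.OrganState(
            kappa1, np.zeros(n), state.ds, np.eye(3), np.zeros(3), 1.0, 0.1
        )
        v = gs.growth_velocity(state, 0.1)
        dt = 0.1
        out = gs.step_curvature(state, (np.zeros(n), np.zeros(n)), v, dt, 0.1)
        ref = kappa1.copy()
        for i in range(n - 1, 0, -1):
            ref[i] = kappa1[i] - dt * v[i] * (kappa1[i] - kappa1[i - 1]) / state.ds
        ref[0] = 0.0
        assert np.allclose(out.kappa1, ref, atol=1e-15)

    def test_proprioception_only_decay(self):
        # Delta = -gamma kappa N: max curvature must never increase.
        # single-signed bump (the discrete max principle at tip CFL = 1
        # admits a sub-percent transient for sign-alternating profiles)
        n = 120
        s = np.arange(n) * 0.01
        kappa1 = 0.8 * np.sin(np.pi * s / s[-1]) ** 2
        kappa1[0] = 0.0
        initial = gs.OrganState(
            kappa1, np.zeros(n), 0.01, np.eye(3), np.zeros(3), 1.0, 0.1
        )
        spec = gs.DifferentialGrowthSpec(proprioception_gamma=0.5, growth_rate=0.1)
        state = initial
        prev = np.hypot(state.kappa1, state.kappa2).max()
        for m in range(100):
            frames, positions = gs.propagate_frames(state)
            delta = gs.differential_growth_vector(
                state, frames, positions, spec, m * 0.1
            )
            v = gs.growth_velocity(state, 0.1)
            state = gs.add_tip_segment(
                gs.step_curvature(state, delta, v, 0.1, 0.1)
            )
            current = np.hypot(state.kappa1, state.kappa2).max()
            assert current <= prev + 1e-14
            prev = current
        assert prev < 0.9 * np.hypot(initial.kappa1, initial.kappa2).max()


class TestAddTipSegment:
    def test_straight_organ_appends_zero(self):
        out = gs.add_tip_segment(_straight())
        assert out.n_segments == 101
        assert out.kappa1[-1] == 0.0 and out.kappa2[-1] == 0.0

    def test_copies_predecessor_curvature(self):
        state = _straight()
        state.kappa1[-1] = 0.5
        state.kappa2[-1] = -0.2
        out = gs.add_tip_segment(state)
        assert out.kappa1[-1] == 0.5 and out.kappa2[-1] == -0.2

    def test_segment_count_after_run(self):
        cfg = gs.SimulationConfig(scenario="custom", n_steps=37, record_every=37)
        rec = gs.run(cfg)
        assert rec.final.state.n_segments == cfg.n_segments0 + 37


class TestStepSizeRelation:
    def test_reference_parameters(self):
        assert gs.step_size_relation(1.0, 0.1, 0.1) == pytest.approx(0.01)

    def test_unit_case_and_linearity(self):
        assert gs.step_size_relation(1.0, 1.0, 1.0) == 1.0
        assert gs.step_size_relation(1.0, 0.2, 0.1) == pytest.approx(
            2 * gs.step_size_relation(1.0, 0.1, 0.1)
        )

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            gs.step_size_relation(0.0, 0.1, 0.1)


class TestDifferentialGrowthVector:
    def test_proprioception_component(self):
        state = _straight()
        state.kappa1[50] = 0.2
        frames, positions = gs.propagate_frames(state)
        spec = gs.DifferentialGrowthSpec(proprioception_gamma=0.01, growth_rate=0.1)
        d1, d2 = gs.differential_growth_vector(state, frames, positions, spec, 0.0)
        assert np.isclose(d1[50], -0.002, atol=1e-15)
        assert np.all(d2 == 0.0)

    def test_circumnutation_at_phase_zero(self):
        state = _straight()
        frames, positions = gs.propagate_frames(state)
        spec = gs.DifferentialGrowthSpec(
            circumnutation=gs.Circumnutation.circular(0.1, 2.0), growth_rate=0.1
        )
        d1, d2 = gs.differential_growth_vector(state, frames, positions, spec, 0.0)
        assert np.allclose(d1, 0.1, atol=1e-15)
        assert np.allclose(d2, 0.0, atol=1e-15)

    def test_twining_composition_matches_direct_formula(self):
        # hand-built curved 3-segment state; compare module output against a
        # direct evaluation of lambda0 z - lambda1 rho_hat - gamma kappa N
        lambda0, lambda1, gamma = 0.1, 0.05, 0.01
        state = gs.OrganState(
            np.array([0.0, 0.6, -0.3]),
            np.array([0.0, 0.2, 0.4]),
            0.1,
            np.eye(3),
            np.array([0.2, -0.1, 0.0]),
            0.3,
            0.05,
        )
        frames, positions = gs.propagate_frames(state)
        cfg = gs.SimulationConfig(
            scenario="line_twine",
            lambda0=lambda0,
            lambda1=lambda1,
            gamma=gamma,
            line_base=(0.5, 0.3, 0.0),
            line_direction=(0.0, 0.0, 1.0),
        )
        spec = gs.build_scenario(cfg)
        d1, d2 = gs.differential_growth_vector(state, frames, positions, spec, 0.0)
        z_hat = np.array([0.0, 0.0, 1.0])
        line_base = np.array([0.5, 0.3, 0.0])
        for n in range(3):
            rel = positions[n] - line_base
            rho = rel - (rel @ z_hat) * z_hat
            rho_hat = rho / np.linalg.norm(rho)
            delta_vec = lambda0 * z_hat - lambda1 * rho_hat
            expected1 = delta_vec @ frames[n, 0] - gamma * state.kappa1[n]
            expected2 = delta_vec @ frames[n, 1] - gamma * state.kappa2[n]
            assert np.isclose(d1[n], expected1, atol=1e-12)
            assert np.isclose(d2[n], expected2, atol=1e-12)


class TestPureElongation:
    def test_stays_exactly_straight(self):
        cfg = gs.SimulationConfig(scenario="custom", n_steps=200, record_every=200)
        rec = gs.run(cfg)
        state = rec.final.state
        assert np.all(state.kappa1 == 0.0) and np.all(state.kappa2 == 0.0)
        assert np.isclose(state.length, cfg.L0 + 200 * cfg.ds, rtol=1e-12)
        assert np.allclose(
            rec.final.tip_position, [0, 0, cfg.L0 + 200 * cfg.ds], atol=1e-10
        )
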