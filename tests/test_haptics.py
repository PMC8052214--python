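"""Force model: needle axis, fulcrum constraint, pop-through, trajectory replay."""

import copy

import numpy as np
import pytest

import vnsim
from vnsim.anatomy import ConfigurationError
from vnsim.haptics import (
    HapticConfig,
    InvalidPoseError,
    NeedleState,
    axial_response,
    fulcrum_force,
    needle_axis,
    pop_threshold,
    simulate_trajectory,
)
from conftest import ideal_trajectory


class TestNeedleAxis:
    def test_pure_vector_quaternion_returns_vector_part(self):
        np.testing.assert_allclose(needle_axis([0, 0, 0, 1]), [0, 0, 1])

    def test_identity_rotation_falls_back_to_rotated_z(self):
        np.testing.assert_allclose(needle_axis([1, 0, 0, 0]), [0, 0, 1])

    def test_mixed_quaternion_normalises_vector_part(self):
        got = needle_axis([0.5, 0.5, 0.5, 0.5])
        np.testing.assert_allclose(got, np.full(3, 1 / np.sqrt(3)), atol=1e-12)

    def test_fallback_only_for_vanishing_vector_part(self):
        # both signs of the identity rotation fall back to the device z-axis
        np.testing.assert_allclose(needle_axis([-1, 0, 0, 0]), [0, 0, 1])
        # any resolvable vector part wins over the fallback
        got = needle_axis([np.sqrt(0.5), np.sqrt(0.5), 0, 0])
        np.testing.assert_allclose(got, [1, 0, 0], atol=1e-12)

    def test_zero_quaternion_rejected(self):
        with pytest.raises(InvalidPoseError):
            needle_axis([0, 0, 0, 0])


class TestFulcrumForce:
    def test_zero_on_axis(self):
        f = fulcrum_force([0, 0, 0], [0, 0, 5], [0, 0, 0, 1], k_fulcrum=0.5)
        np.testing.assert_allclose(f, [0, 0, 0], atol=1e-12)

    def test_lateral_offset_restoring_force(self):
        # p=(1,0,2) off the z axis: projection p'=(0,0,2), F = k(p'-p)
        f = fulcrum_force([0, 0, 0], [1, 0, 2], [0, 0, 0, 1], k_fulcrum=0.5)
        np.testing.assert_allclose(f, [-0.5, 0, 0], atol=1e-12)
        assert np.linalg.norm(f) == pytest.approx(0.5)

    def test_literal_sign_flag_flips_direction(self):
        f = fulcrum_force([0, 0, 0], [1, 0, 2], [0, 0, 0, 1], 0.5, literal_sign=True)
        np.testing.assert_allclose(f, [0.5, 0, 0], atol=1e-12)

    def test_orthogonal_to_axis_random_poses(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            r = rng.normal(scale=10, size=3)
            p = rng.normal(scale=10, size=3)
            f = fulcrum_force(r, p, q, k_fulcrum=0.7)
            assert abs(np.dot(f, needle_axis(q))) < 1e-9

    def test_magnitude_equals_k_times_distance_to_line(self):
        # independent oracle: least-squares distance from p to the line
        rng = np.random.default_rng(1)
        for _ in range(200):
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            r = rng.normal(scale=5, size=3)
            p = rng.normal(scale=5, size=3)
            axis = needle_axis(q)
            t, *_ = np.linalg.lstsq(axis[:, None], (p - r)[:, None], rcond=None)
            dist = np.linalg.norm(p - (r + float(t[0][0]) * axis))
            f = fulcrum_force(r, p, q, k_fulcrum=1.3)
            assert np.linalg.norm(f) == pytest.approx(1.3 * dist, abs=1e-9)


class TestPopThreshold:
    def test_scales_with_f_max(self):
        assert pop_threshold(0.02, 3.3) == pytest.approx(0.066)
        assert pop_threshold(1.0, 3.3) == pytest.approx(3.3)

    def test_zero_disables_membrane(self):
        assert pop_threshold(0.0, 99.0) == 0.0

    def test_strictly_increasing_in_pop_through(self):
        ts = [pop_threshold(p, 3.3) for p in np.linspace(0.01, 1, 50)]
        assert all(b > a for a, b in zip(ts, ts[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            pop_threshold(1.5, 3.3)
        with pytest.raises(ConfigurationError):
            pop_threshold(0.5, -1.0)


def _state(depth):
    return NeedleState(p=[0, 0, -depth], Q=[0, 0, 0, 1], depth=depth)


class TestAxialResponse:
    def test_full_traversal_fires_exactly_two_distinct_pops(self, wall_only):
        config = HapticConfig()
        popped = set()
        events = []
        for depth in np.linspace(-1.0, 27.0, 400):
            *_, ev = axial_response(_state(depth), wall_only.layers, 1.0, config, popped)
            events.extend(ev)
        distinct = [e for e in events if e.distinct]
        assert [e.layer for e in distinct] == ["linea_alba", "peritoneum"]
        # skin puncture recorded but not counted as a clinical pop
        assert [e.layer for e in events if not e.distinct] == ["skin"]

    def test_stationary_in_fat_all_forces_zero(self, wall_only):
        popped = {"skin"}
        spring, damping, friction, ev = axial_response(
            _state(10.0), wall_only.layers, 0.0, HapticConfig(), popped
        )
        assert spring == damping == friction == 0.0
        assert ev == []

    def test_membrane_spring_monotone_then_releases(self, wall_only):
        # approach linea alba with increasing penetration: |spring| grows
        # monotonically until the pop, then drops to zero
        config = HapticConfig()
        popped = {"skin"}
        mags = []
        popped_at = None
        for depth in np.arange(23.0, 23.5, 0.01):
            spring, *_, ev = axial_response(_state(depth), wall_only.layers, 1.0,
                                            config, popped)
            if any(e.layer == "linea_alba" for e in ev):
                popped_at = depth
                assert spring == 0.0
                break
            mags.append(-spring)
        assert popped_at is not None
        assert all(b > a for a, b in zip(mags, mags[1:]))
        # threshold crossed exactly at pop_through * f_max / (scale * stiffness)
        expected_pen = 0.02 * config.f_max / (config.stiffness_scale * 0.5)
        assert popped_at - 23.0 == pytest.approx(expected_pen, abs=0.011)

    def test_friction_static_below_deadband_dynamic_above(self, wall_only):
        config = HapticConfig()
        popped = {"skin", "linea_alba", "peritoneum"}
        d = 25.5  # inside the peritoneum bulk (friction 0.35)
        _, _, fric_slow, _ = axial_response(_state(d), wall_only.layers, 0.05,
                                            config, set(popped))
        _, _, fric_fast, _ = axial_response(_state(d), wall_only.layers, 2.0,
                                            config, set(popped))
        assert fric_slow == 0.0
        assert fric_fast == pytest.approx(-0.35 * config.friction_scale)
        _, _, fric_back, _ = axial_response(_state(d), wall_only.layers, -2.0,
                                            config, set(popped))
        assert fric_back == pytest.approx(+0.35 * config.friction_scale)

    def test_damping_proportional_to_velocity(self, wall_only):
        config = HapticConfig()
        popped = {"skin"}
        d = 1.5  # skin bulk, damping 0.1
        _, f1, _, _ = axial_response(_state(d), wall_only.layers, 1.0, config, set(popped))
        _, f2, _, _ = axial_response(_state(d), wall_only.layers, 2.0, config, set(popped))
        assert f1 == pytest.approx(-0.1 * config.damping_scale * 1.0)
        assert f2 == pytest.approx(2 * f1)


class TestSimulateTrajectory:
    def test_nominal_insertion_two_pops_no_contacts(self, anatomy, ideal_profile):
        traj = vnsim.generate_attempt(ideal_profile, anatomy, "A", seed=3)
        sim = simulate_trajectory(anatomy, traj)
        assert [e.layer for e in sim.distinct_pops] == ["linea_alba", "peritoneum"]
        assert sim.forbidden_contacts == []
        assert len(sim.t) == len(traj.samples)

    def test_trajectory_never_touching_skin_is_force_free(self, anatomy):
        samples = [
            vnsim.PoseSample(t=float(i), position=[0, 0, 5 + i], quaternion=[0, 0, 0, 1])
            for i in range(5)
        ]
        sim = simulate_trajectory(anatomy, vnsim.Trajectory(samples=samples))
        np.testing.assert_allclose(sim.f_total, 0.0)
        assert sim.pops == [] and sim.contacts == []
        assert set(sim.layer) == {"outside"}

    def test_overshoot_into_bowel_logs_forbidden_contact(self, anatomy):
        prof = vnsim.TraineeProfile(angle_bias=0, angle_sd=0, overshoot_prob=1.0,
                                    speed_jitter_sd=0, lateral_tremor_sd=0)
        traj = vnsim.generate_attempt(prof, anatomy, "A", seed=5)
        sim = simulate_trajectory(anatomy, traj)
        assert any(c.organ == "bowel" for c in sim.forbidden_contacts)

    def test_force_decomposition_sums_to_total(self, anatomy, ideal_profile):
        traj = vnsim.generate_attempt(ideal_profile, anatomy, "A", seed=9)
        sim = simulate_trajectory(anatomy, traj)
        np.testing.assert_allclose(
            sim.f_total,
            sim.f_fulcrum + sim.f_axial_spring + sim.f_damping + sim.f_friction,
            atol=1e-9,
        )

    def test_bitwise_deterministic(self, anatomy, ideal_profile):
        traj = vnsim.generate_attempt(ideal_profile, anatomy, "A", seed=11)
        s1 = simulate_trajectory(anatomy, traj)
        s2 = simulate_trajectory(anatomy, copy.deepcopy(traj))
        np.testing.assert_array_equal(s1.f_total, s2.f_total)
        assert [(e.t, e.layer) for e in s1.pops] == [(e.t, e.layer) for e in s2.pops]

    def test_rejects_non_monotone_timestamps(self, anatomy):
        samples = [
            vnsim.PoseSample(t=0.0, position=[0, 0, 5], quaternion=[0, 0, 0, 1]),
            vnsim.PoseSample(t=1.0, position=[0, 0, 4], quaternion=[0, 0, 0, 1]),
        ]
        traj = vnsim.Trajectory(samples=samples)
        traj.samples[1] = vnsim.PoseSample(t=0.0, position=[0, 0, 4],
                                           quaternion=[0, 0, 0, 1])
        with pytest.raises(ValueError, match="strictly increasing"):
            simulate_trajectory(anatomy, traj)

    def test_spring_conservative_over_closed_cycle_without_pops(self, wall_only):
        # zero damping/friction, no membranes popped: the axial spring work
        # over a closed depth excursion cancels to numerical precision
        from dataclasses import replace

        layers = [replace(l, damping=0.0, static_friction=0.0, dynamic_friction=0.0,
                          pop_through=0.0)
                  for l in wall_only.layers]
        layers = [replace(layers[0], pop_through=0.9, stiffness=0.4)] + layers[1:]
        anatomy = vnsim.Anatomy(layers=layers)
        depths = np.concatenate([np.linspace(-1, 2.0, 150), np.linspace(2.0, -1, 150)[1:]])
        ts = np.arange(len(depths)) * 0.01
        samples = [
            vnsim.PoseSample(t=float(t), position=[0, 0, -d], quaternion=[0, 0, 0, 1])
            for t, d in zip(ts, depths)
        ]
        sim = simulate_trajectory(anatomy, vnsim.Trajectory(samples=samples))
        assert sim.pops == []  # never reaches the raised threshold
        # net work = sum F_axial . displacement over the closed cycle
        axial = sim.f_axial_spring[:, 2]  # skin-frame z component
        dz = np.diff(-depths)
        work = float(np.sum(0.5 * (axial[1:] + axial[:-1]) * -dz))
        assert abs(work) < 1e-6

    def test_empty_trajectory_rejected(self, anatomy):
        with pytest.raises(ValueError, match="empty"):
            simulate_trajectory(anatomy, vnsim.Trajectory(samples=[]))


class TestNeedleState:
    def test_rejects_non_unit_quaternion(self):
        with pytest.raises(InvalidPoseError):
            NeedleState(p=[0, 0, 0], Q=[0.5, 0, 0, 0])


def test_ideal_trajectory_helper_matches_reference_angle(anatomy):
    traj = ideal_trajectory(anatomy)
    freeze = traj.sample_at_event("freeze")
    axis = needle_axis(freeze.quaternion)
    assert vnsim.insertion_angle(axis, anatomy.skin_frame) == pytest.approx(45.0)
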