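"""Plant mechanics: geometry, tensions, torques, statics and integration."""

import numpy as np
import pytest

from bioeye.plant import (MUSCLES, EyeState, MuscleGeometry, Plant,
                          PlantParameters, default_plant)
from bioeye.rotation import angles_from_rotvec


def _hold(plant):
    return plant.solve_fixation_tensions(np.zeros(3))


def _mirror_toy_plant():
    """Two horizontal antagonists mirrored about the x-z plane, plus four
    weak symmetric placeholders, for symmetry arguments."""
    r = 12.0
    a = np.radians(50.0)
    muscles = [
        MuscleGeometry("LR", np.array([r * np.cos(a), -r * np.sin(a), 0.0]),
                       np.array([-34.0, 0.0, 0.0])),
        MuscleGeometry("MR", np.array([r * np.cos(a), r * np.sin(a), 0.0]),
                       np.array([-34.0, 0.0, 0.0])),
        MuscleGeometry("SR", np.array([r * np.cos(a), 0.0, r * np.sin(a)]),
                       np.array([-34.0, 0.0, 0.0])),
        MuscleGeometry("IR", np.array([r * np.cos(a), 0.0, -r * np.sin(a)]),
                       np.array([-34.0, 0.0, 0.0])),
        MuscleGeometry("SO", np.array([-r * 0.4, 0.0, r * 0.9165]),
                       np.array([6.0, 0.0, 12.0]), is_pulley=True),
        MuscleGeometry("IO", np.array([-r * 0.4, 0.0, -r * 0.9165]),
                       np.array([6.0, 0.0, -12.0]), is_pulley=True),
    ]
    return Plant(muscles, PlantParameters())


class TestGeometry:
    def test_path_length_at_reference(self, plant):
        for name in MUSCLES:
            _, L = plant.muscle_direction(name, np.zeros(3))
            i = plant.muscle_index(name)
            expect = np.linalg.norm(plant._anch[:, i] - plant._ins[:, i])
            assert L == pytest.approx(expect)

    def test_rotation_toward_pull_shortens_path(self, plant):
        """Abducting the right eye (rightward, -z) rotates the temporal LR
        insertion toward the posterior origin: its path shortens."""
        _, L0 = plant.muscle_direction("LR", np.zeros(3))
        _, L1 = plant.muscle_direction("LR", np.array([0.0, 0.0, -0.15]))
        assert L1 < L0

    def test_pulley_routed_direction(self, plant):
        """SO pulls toward its trochlea-like pulley (anterior-nasal-superior),
        not toward the posterior recti origin."""
        d, _ = plant.muscle_direction("SO", np.zeros(3))
        assert d[0] > 0 and d[1] > 0 and d[2] > 0

    def test_insertions_on_sphere(self, plant):
        norms = np.linalg.norm(plant._ins, axis=0)
        np.testing.assert_allclose(norms, plant.params.globe_radius)


class TestTension:
    def test_pretension_at_reference(self, plant):
        for name in MUSCLES:
            assert plant.tendon_tension(name, np.zeros(3), 0.0) == \
                pytest.approx(plant.params.pretension)

    def test_slack_clamp(self, plant):
        assert plant.tendon_tension("LR", np.zeros(3), -50.0) == 0.0

    def test_linear_region_slope_is_stiffness(self, plant):
        t1 = plant.tendon_tension("MR", np.zeros(3), 0.5)
        t2 = plant.tendon_tension("MR", np.zeros(3), 1.5)
        assert t2 - t1 == pytest.approx(plant.params.stiffness)


class TestNetTorque:
    def test_zero_tension_zero_omega_gives_zero(self, plant):
        st = EyeState()
        tau = plant.net_torque(st, np.full(6, -100.0))  # everything slack
        np.testing.assert_allclose(tau, 0.0)

    def test_single_lr_torque_is_temporalward(self, plant):
        """A lone taut LR on the right eye at reference pulls the gaze
        temporally (rightward = negative z torque)."""
        u = np.full(6, -100.0)
        u[plant.muscle_index("LR")] = 102.0  # only LR taut
        tau = plant.net_torque(EyeState(), u)
        assert tau[2] < 0
        assert abs(tau[2]) > abs(tau[0]) and abs(tau[2]) > abs(tau[1])

    def test_mirror_symmetric_cocontraction_cancels_z(self):
        toy = _mirror_toy_plant()
        u = np.full(6, -100.0)
        u[0] = u[1] = 101.0  # equal LR/MR co-contraction, others slack
        tau = toy.net_torque(EyeState(), u)
        assert tau[2] == pytest.approx(0.0, abs=1e-9)


class TestStatics:
    def test_zero_torque_at_solution(self, plant):
        for r in (np.zeros(3), np.array([0.0, 0.15, -0.1]),
                  np.array([0.0, -0.25, 0.2])):
            u = plant.solve_fixation_tensions(r)
            tau = plant.net_torque(EyeState(r), u)
            assert np.linalg.norm(tau) < 1e-6

    def test_tensions_above_floor(self, plant):
        for r in (np.array([0.0, 0.28, 0.0]), np.array([0.0, -0.2, -0.2])):
            u = plant.solve_fixation_tensions(r)
            tens = plant.tensions(EyeState(r), u)
            assert tens.min() >= plant.params.tension_floor - 1e-9

    def test_mirror_symmetric_geometry_equal_commands(self):
        toy = _mirror_toy_plant()
        u = toy.solve_fixation_tensions(np.zeros(3))
        assert u[0] == pytest.approx(u[1], abs=1e-8)

    def test_lr_static_tension_exceeds_mr(self, plant):
        """With the recti origin displaced nasally, the LR path at the
        reference fixation is longer and its static tension higher."""
        u = plant.solve_fixation_tensions(np.zeros(3))
        tens = plant.tensions(EyeState(), u)
        assert tens[plant.muscle_index("LR")] > tens[plant.muscle_index("MR")]

    def test_infeasible_orientation_raises(self, plant):
        with pytest.raises(RuntimeError):
            plant.solve_fixation_tensions(np.array([0.0, -0.3, -0.3]))


class TestDynamics:
    def test_equilibrium_is_stationary(self, plant):
        u0 = _hold(plant)
        st = EyeState()
        nxt = plant.step(st, u0)
        np.testing.assert_allclose(nxt.r, 0.0, atol=1e-14)
        np.testing.assert_allclose(nxt.w, 0.0, atol=1e-12)

    def test_free_decay_monotone_speed(self, plant):
        """From a spun-up state under holding commands, the overdamped plant
        dissipates speed monotonically (after the first viscous relaxation)."""
        u0 = _hold(plant)
        T = 150
        u = np.repeat(u0[:, None], T, axis=1)
        traj = plant.simulate(u, EyeState(np.zeros(3), np.array([0, 0, 3.0])))
        speed = np.linalg.norm(traj.w, axis=1)
        # skip the first few samples where axis cross-coupling mixes modes
        assert np.all(np.diff(speed[5:]) <= 1e-9)

    def test_simulation_deterministic(self, plant):
        u0 = _hold(plant)
        u = np.repeat(u0[:, None], 100, axis=1)
        u[0] += 2.0
        t1 = plant.simulate(u)
        t2 = plant.simulate(u)
        assert np.array_equal(t1.r, t2.r) and np.array_equal(t1.w, t2.w)

    def test_tensions_never_negative(self, plant, rng):
        u0 = _hold(plant)
        u = np.repeat(u0[:, None], 200, axis=1)
        u += rng.normal(0, 2.0, u.shape).cumsum(axis=1) * 0.05
        traj = plant.simulate(np.clip(u, -8, 12))
        assert traj.tensions.min() >= 0.0

    def test_step_response_no_overshoot(self, plant):
        """Command steps on either horizontal rectus produce monotone
        gaze displacement without overshoot (overdamped plant)."""
        u0 = _hold(plant)
        for muscle, sign in (("LR", 1), ("MR", -1)):
            u = np.repeat(u0[:, None], 400, axis=1)
            u[plant.muscle_index(muscle)] += 2.5
            traj = plant.simulate(u)
            th = np.array([angles_from_rotvec(r)[0] for r in traj.r]) * sign
            assert th[-1] > 1.0
            assert th.max() <= th[-1] + 1e-9

    def test_doubled_damping_slows_settling(self, plant):
        import dataclasses
        u0 = _hold(plant)
        u = np.repeat(u0[:, None], 600, axis=1)
        u[0] += 2.0

        def t95(pl):
            traj = pl.simulate(u)
            th = np.array([angles_from_rotvec(r)[0] for r in traj.r])
            return np.argmax(th >= 0.95 * th[-1])

        slow = Plant(plant.muscles, dataclasses.replace(
            plant.params, damping=2 * plant.params.damping))
        assert t95(slow) > t95(plant)

    def test_divergence_detected(self, plant):
        with pytest.raises((FloatingPointError, ValueError)):
            plant.simulate(np.full((6, 10), np.nan))

    def test_isotropic_inertia_constant_in_head_frame(self):
        from bioeye import _engine
        iso = np.array([0.44, 0.44, 0.44])
        I0 = _engine._inertia_head(np.zeros(3), iso)
        I1 = _engine._inertia_head(np.array([0.2, -0.1, 0.3]), iso)
        np.testing.assert_allclose(I0, I1, atol=1e-12)

    def test_semi_implicit_matches_rk4_reference(self, plant):
        """Default integrator within 0.1% of a fine-substepped RK4 over
        100 ms, on a step-driven movement."""
        u0 = _hold(plant)
        u = np.repeat(u0[:, None], 101, axis=1)
        u[0] += 3.0
        u[2] -= 1.0
        t_euler = plant.simulate(u)
        t_rk4 = plant.simulate_rk4(u)
        scale = np.abs(t_rk4.r).max()
        assert np.abs(t_euler.r - t_rk4.r).max() / scale < 1e-3


class TestConstruction:
    def test_requires_six_named_muscles(self):
        with pytest.raises(ValueError):
            Plant([], PlantParameters())

    def test_insertion_off_sphere_rejected(self):
        bad = [MuscleGeometry(n, np.array([30.0, 0.0, 0.0]),
                              np.array([-34.0, 0.0, 0.0])) for n in MUSCLES]
        with pytest.raises(ValueError):
            Plant(bad, PlantParameters())

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            PlantParameters(damping=-1.0)

    def test_default_plant_loads(self, plant):
        assert tuple(m.name for m in plant.muscles) == MUSCLES
        assert plant.muscles[plant.muscle_index("SO")].is_pulley
        assert plant.muscles[plant.muscle_index("IO")].is_pulley
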