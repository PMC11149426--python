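"""Analysis suite: metrics, fits, curvature, Listing plane, cross-coupling."""

import numpy as np
import pytest

from bioeye import analysis as an
from bioeye.plant import Trajectory
from bioeye.rotation import relative_rotation, rotation_angle_deg, \
    rotvec_from_angles


def _traj_from_angles(ang_deg, dt_ms=1.0):
    """Trajectory whose gaze path follows the given (T,2) angle trace,
    with omega set from the horizontal/vertical rates (torsion-free)."""
    ang = np.asarray(ang_deg, dtype=float)
    T = ang.shape[0]
    r = np.stack([rotvec_from_angles(a[0], a[1]) for a in ang])
    vel = np.gradient(np.radians(ang), dt_ms / 1e3, axis=0)
    w = np.zeros((T, 3))
    w[:, 2] = -vel[:, 0]   # theta_H = -2 atan r_z; small-angle omega proxy
    w[:, 1] = -vel[:, 1]
    z6 = np.zeros((T, 6))
    return Trajectory(np.arange(T) * dt_ms, r, w, np.zeros((T, 3)), z6, z6.T.copy())


class TestSaccadeMetrics:
    def test_pure_horizontal(self):
        ang = np.column_stack([np.linspace(0, 10, 100), np.zeros(100)])
        m = an.saccade_metrics(_traj_from_angles(ang), duration_ms=99)
        assert m.amplitude == pytest.approx(10.0, abs=1e-9)
        assert m.direction == pytest.approx(0.0, abs=1e-9)
        assert m.duration_ms == 99

    def test_minimum_jerk_peak_velocity_closed_form(self):
        """V_PK of a minimum-jerk 20 deg / 100 ms profile is 1.875 A/D."""
        D = 0.1
        t = np.linspace(0, 1, 101)
        pos = 20.0 * (10 * t ** 3 - 15 * t ** 4 + 6 * t ** 5)
        ang = np.column_stack([pos, np.zeros_like(pos)])
        m = an.saccade_metrics(_traj_from_angles(ang), speed_from="omega")
        expect = 1.875 * 20.0 / D
        assert m.v_peak_h == pytest.approx(expect, rel=0.01)

    def test_relative_rotation_amplitude_agrees_with_angle_difference(self, rng):
        """Inside the oculomotor range the angle of the relative rotation
        between endpoint orientations tracks the gaze-angle chord
        sqrt(dH^2+dV^2): to <1% for starts within 15 deg of centre, and to
        <5% over the full +/-27 deg range (rotations do not commute, so the
        charts genuinely drift apart at eccentric starts)."""
        for ecc, tol in ((15.0, 0.01), (27.0, 0.05)):
            for _ in range(50):
                a0 = rng.uniform(-ecc, ecc, 2)
                a1 = rng.uniform(-ecc, ecc, 2)
                r0 = rotvec_from_angles(*a0)
                r1 = rotvec_from_angles(*a1)
                amp_q = rotation_angle_deg(relative_rotation(r0, r1))
                amp_c = np.hypot(*(a1 - a0))
                if amp_c < 2.0:
                    continue
                assert amp_q == pytest.approx(amp_c, rel=tol)


class TestAccuracyRegression:
    def test_perfect_responses(self, rng):
        t = rng.uniform(-25, 25, (40, 2))
        fit = an.accuracy_regression(t, t)
        assert fit.b == pytest.approx(1.0) and fit.d == pytest.approx(1.0)
        assert fit.a == pytest.approx(0.0, abs=1e-9)
        assert fit.r2_h == pytest.approx(1.0)

    def test_gain_recovery(self, rng):
        t = rng.uniform(-25, 25, (60, 2))
        fit = an.accuracy_regression(t, 0.9 * t)
        assert fit.b == pytest.approx(0.9, abs=1e-9)
        assert fit.d == pytest.approx(0.9, abs=1e-9)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            an.accuracy_regression(np.zeros((5, 2)), np.zeros((4, 2)))


class TestMainSequence:
    def test_exact_recovery_from_synthetic(self, rng):
        e, f, k, m = 20.0, 2.0, 0.0, 1.6
        R = rng.uniform(2, 30, 80)
        D = e + f * R                      # ms
        V = (k + m * R) / (D / 1e3)        # deg/s
        fit = an.main_sequence_fit(R, D, V)
        assert fit.e == pytest.approx(e, abs=1e-8)
        assert fit.f == pytest.approx(f, abs=1e-9)
        assert fit.k == pytest.approx(k, abs=1e-8)
        assert fit.m == pytest.approx(m, abs=1e-9)
        assert fit.saturation_velocity == pytest.approx(1e3 * m / f)

    def test_predict_vpk_saturates_at_m_over_f(self):
        fit = an.MainSequenceFit(e=20.0, f=2.0, k=0.0, m=1.6,
                                 r2_duration=1.0, r2_product=1.0)
        v_large = an.predict_vpk(np.array([1e9]), fit)[0]
        assert v_large == pytest.approx(fit.saturation_velocity, rel=1e-6)

    def test_predict_vpk_zero_at_zero(self):
        fit = an.MainSequenceFit(20.0, 2.0, 0.0, 1.6, 1.0, 1.0)
        assert an.predict_vpk(np.array([1e-9]), fit)[0] == pytest.approx(0.0, abs=1e-3)


class TestCurvature:
    def test_straight_segment_any_direction(self, rng):
        for _ in range(10):
            phi = rng.uniform(0, 2 * np.pi)
            t = np.linspace(0, 15, 60)
            ang = np.column_stack([t * np.cos(phi), t * np.sin(phi)])
            ang += rng.uniform(-10, 10, 2)
            res = an.curvature(ang)
            assert res.c == pytest.approx(0.0, abs=1e-9)
            assert res.label == "straight"

    def test_rightward_semicircle_first_quadrant(self):
        th = np.linspace(np.pi, 0, 201)  # includes the apex exactly
        A = 8.0
        ang = np.column_stack([A / 2 * (1 + np.cos(th)), A / 2 * np.sin(th)])
        res = an.curvature(ang)
        assert res.c == pytest.approx(-0.5, abs=1e-9)
        assert res.label == "curved"

    def test_single_bump_height_over_run(self):
        A, h = 20.0, 1.0
        x = np.linspace(0, A, 201)  # includes the apex exactly
        ang = np.column_stack([x, h * np.sin(np.pi * x / A)])
        res = an.curvature(ang)
        assert abs(res.c) == pytest.approx(h / A, abs=1e-9)
        assert res.c == pytest.approx(-h / A)  # upward arc, rightward run

    def test_invariance_to_rotation_and_translation(self, rng):
        x = np.linspace(0, 10, 120)
        ang = np.column_stack([x, 0.8 * np.sin(np.pi * x / 10)])
        c0 = an.curvature(ang).c
        for _ in range(5):
            phi = rng.uniform(0, 2 * np.pi)
            Rm = np.array([[np.cos(phi), -np.sin(phi)],
                           [np.sin(phi), np.cos(phi)]])
            moved = ang @ Rm.T + rng.uniform(-20, 20, 2)
            assert an.curvature(moved).c == pytest.approx(c0, abs=1e-9)

    def test_reflection_flips_sign(self):
        x = np.linspace(0, 10, 120)
        ang = np.column_stack([x, 0.8 * np.sin(np.pi * x / 10)])
        mirrored = ang * np.array([1.0, -1.0])
        assert an.curvature(mirrored).c == pytest.approx(-an.curvature(ang).c)

    def test_zero_amplitude_rejected(self):
        with pytest.raises(ValueError):
            an.curvature(np.zeros((10, 2)))

    def test_classification_thresholds(self):
        assert an.CurvatureResult.classify(0.01) == "straight"
        assert an.CurvatureResult.classify(0.08) == "intermediate"
        assert an.CurvatureResult.classify(-0.2) == "curved"


class TestListingPlane:
    def test_exact_plane_recovered(self, rng):
        alpha, beta = -0.116, -0.02
        yz = rng.uniform(-0.3, 0.3, (500, 2))
        r = np.column_stack([alpha * yz[:, 0] + beta * yz[:, 1], yz])
        fit = an.fit_listing_plane(r)
        assert fit.alpha == pytest.approx(alpha, abs=1e-12)
        assert fit.beta == pytest.approx(beta, abs=1e-12)
        assert fit.sigma == pytest.approx(0.0, abs=1e-12)

    def test_noise_sd_recovered_monte_carlo(self, rng):
        s = 0.01
        yz = rng.uniform(-0.3, 0.3, (10_000, 2))
        rx = 0.1 * yz[:, 0] + rng.normal(0, s, 10_000)
        fit = an.fit_listing_plane(np.column_stack([rx, yz]))
        assert fit.sigma == pytest.approx(s, rel=0.05)

    def test_tilt_of_printed_coefficient(self, rng):
        yz = rng.uniform(-0.3, 0.3, (200, 2))
        r = np.column_stack([-0.116 * yz[:, 0], yz])
        fit = an.fit_listing_plane(r)
        assert fit.tilt_deg == pytest.approx(6.617, abs=0.01)

    def test_sigma_deg_is_double_arctan(self):
        fit = an.ListingPlaneFit(0, 0, 0.075, 0.0, 0, 0, 10)
        # conversion applied by the constructor path:
        assert np.degrees(2 * np.arctan(0.075)) == pytest.approx(8.58, abs=0.01)

    def test_order_invariance(self, rng):
        yz = rng.uniform(-0.3, 0.3, (300, 2))
        r = np.column_stack([0.05 * yz[:, 0] + rng.normal(0, 0.005, 300), yz])
        f1 = an.fit_listing_plane(r)
        f2 = an.fit_listing_plane(r[rng.permutation(300)])
        assert f1.tilt_deg == pytest.approx(f2.tilt_deg)
        assert f1.sigma == pytest.approx(f2.sigma)


class TestComponentCoupling:
    def test_proportional_components_correlate_perfectly(self):
        t = np.linspace(0, 1, 100)
        prof = np.sin(np.pi * t) ** 2
        ang = np.column_stack([np.cumsum(prof), 0.5 * np.cumsum(prof)])
        tr = _traj_from_angles(ang)
        m = an.saccade_metrics(tr)
        df = an.component_coupling([tr], [m])
        assert df["corr_hv"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_reduces_to_vectorial_relation_at_phi_zero(self):
        fit = an.MainSequenceFit(20.0, 2.0, 0.0, 1.6, 1.0, 1.0)
        amps = np.array([5.0, 10.0, 20.0])
        for A in amps:
            assert an.common_source_prediction(A, 0.0, fit, "h") == \
                pytest.approx(float(an.predict_vpk(np.array([A]), fit)[0]))

    def test_cosine_scaling_at_fixed_component(self):
        fit = an.MainSequenceFit(20.0, 2.0, 0.0, 1.6, 1.0, 1.0)
        phis = np.array([0.0, 30.0, 60.0])
        v = an.common_source_prediction(12.0, phis, fit, "h")
        np.testing.assert_allclose(v / v[0], np.cos(np.radians(phis)),
                                   atol=1e-12)


class TestPositionGain:
    def test_constructed_coefficients_recovered(self, rng):
        n = 400
        dh = rng.uniform(6, 25, n) * rng.choice([-1, 1], n)
        hon = rng.uniform(-15, 15, n)
        amp = np.abs(dh)
        contra = -np.sign(dh) * hon
        z = lambda x: (x - x.mean()) / x.std(ddof=1)
        v = 0.7 * z(amp) + 0.4 * z(contra) + rng.normal(0, 0.05, n)
        vpk = 300 + 50 * v  # arbitrary de-standardization
        fit = an.position_gain_regression(dh, hon, vpk)
        # the regression standardizes the response too, so the generating
        # coefficients are recovered up to the 1/sd(v) rescaling
        sv = v.std(ddof=1)
        assert fit.g_r2 == pytest.approx(0.7 / sv, abs=0.03)
        assert fit.g_hon == pytest.approx(0.4 / sv, abs=0.03)
        assert fit.f_pvalue < 1e-6
        assert fit.r2_full > fit.r2_amp

    def test_amplitude_cutoff_applied(self, rng):
        dh = np.concatenate([rng.uniform(6, 20, 50), rng.uniform(0.1, 5, 50)])
        hon = rng.uniform(-10, 10, 100)
        v = 20 * np.abs(dh) + rng.normal(0, 5, 100)
        fit = an.position_gain_regression(dh, hon, v)
        assert fit.n == 50

    def test_zero_variance_regressor_rejected(self):
        dh = np.full(30, 10.0)
        with pytest.raises(ValueError, match="zero-variance"):
            an.position_gain_regression(dh, np.zeros(30), np.full(30, 100.0))


class TestSynergies:
    def test_identical_and_negated_signals(self):
        T = 80
        u = np.zeros((6, T))
        u[0] = np.sin(np.linspace(0, np.pi, T))
        u[1] = -u[0]
        u[2] = u[0].copy()
        z = np.zeros((T, 6))
        tr = Trajectory(np.arange(T, dtype=float), np.zeros((T, 3)),
                        np.zeros((T, 3)), np.zeros((T, 3)), z, u)
        res = an.synergy_correlations([tr], pairs=(("LR", "MR"), ("LR", "SR")))
        assert res.per_saccade["LR-MR"].iloc[0] == pytest.approx(-1.0)
        assert res.per_saccade["LR-SR"].iloc[0] == pytest.approx(1.0)
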