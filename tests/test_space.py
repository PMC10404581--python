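"""Horizontal frame, Lie brackets, bracket-generating rank, integral curves."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

import srmotion as sm
from srmotion.distance import wrap_difference
from srmotion.space import FIELD_NAMES, vector_field


def kp(t=0.0, x=0.0, y=0.0, theta=0.0, v=1.0, a=0.0):
    return sm.KinPoint(t, x, y, theta, v, a)


finite_coord = st.floats(-10, 10, allow_nan=False)
points = st.builds(kp, finite_coord, finite_coord, finite_coord,
                   st.floats(0, 2 * np.pi - 1e-9), finite_coord, finite_coord)


class TestFrame:
    @pytest.mark.parametrize("point, expected_x1", [
        (kp(theta=0.0, v=1.0, a=0.0), [1, 1, 0, 0, 0, 0]),
        (kp(theta=np.pi / 2, v=2.0, a=3.0), [1, 0, 2, 0, 3, 0]),
    ])
    def test_x1_carries_kinematic_constraints(self, point, expected_x1):
        x1, _, _ = sm.horizontal_frame(point)
        np.testing.assert_allclose(x1, expected_x1, atol=1e-15)

    def test_x2_x3_are_constant_coordinate_fields(self, rng):
        for _ in range(5):
            p = kp(*rng.normal(size=3), rng.uniform(0, 2 * np.pi),
                   rng.uniform(0, 2), rng.normal())
            _, x2, x3 = sm.horizontal_frame(p)
            np.testing.assert_array_equal(x2, [0, 0, 0, 1, 0, 0])
            np.testing.assert_array_equal(x3, [0, 0, 0, 0, 0, 1])

    def test_non_finite_point_rejected(self):
        with pytest.raises(ValueError):
            sm.KinPoint(0, np.nan, 0, 0, 1, 0)


class TestBrackets:
    @pytest.mark.parametrize("f, g, point, expected", [
        ("X1", "X2", kp(theta=0.0, v=1.0), [0, 0, -1, 0, 0, 0]),
        ("X3", "X1", kp(), [0, 0, 0, 0, 1, 0]),
        ("X3", "X1", kp(theta=2.0, v=3.0, a=-1.0), [0, 0, 0, 0, 1, 0]),
        ("X5", "X1", kp(theta=np.pi / 2), [0, 0, 1, 0, 0, 0]),
    ])
    def test_structural_brackets(self, f, g, point, expected):
        np.testing.assert_allclose(sm.lie_bracket(f, g, point), expected,
                                   atol=1e-12)

    def test_bracket_equals_named_field(self, rng):
        # [X1,X2]=X4, [X3,X1]=X5, [X5,X1]=X6 hold at arbitrary points
        for _ in range(10):
            p = kp(rng.normal(), rng.normal(), rng.normal(),
                   rng.uniform(0, 2 * np.pi), rng.uniform(-2, 2), rng.normal())
            for (f, g), name in [(("X1", "X2"), "X4"), (("X3", "X1"), "X5"),
                                 (("X5", "X1"), "X6")]:
                np.testing.assert_allclose(sm.lie_bracket(f, g, p),
                                           vector_field(name, p), atol=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(points, st.sampled_from(FIELD_NAMES), st.sampled_from(FIELD_NAMES))
    def test_antisymmetry(self, p, f, g):
        np.testing.assert_allclose(sm.lie_bracket(f, g, p),
                                   -sm.lie_bracket(g, f, p), atol=1e-12)

    def test_unknown_field_rejected(self):
        with pytest.raises(ValueError):
            sm.lie_bracket("X1", "X7", kp())


class TestHormanderRank:
    def test_full_rank_off_the_zero_speed_set(self, rng):
        for _ in range(100):
            v = rng.uniform(0.05, 3.0) * rng.choice([-1, 1])
            p = kp(rng.normal(), rng.normal(), rng.normal(),
                   rng.uniform(0, 2 * np.pi), v, rng.normal())
            assert sm.hormander_rank(p) == 6

    def test_rank_drops_where_speed_vanishes(self):
        assert sm.hormander_rank(kp(v=0.0, a=0.0)) == 5
        assert sm.hormander_rank(kp(v=0.0, a=2.0, theta=1.0)) == 5


class TestIntegralCurves:
    def test_linear_pd_closed_form(self):
        spec = sm.CurveSpec((0.5, 0, 0, 0, 0), (0, 0, 0), kp(), 1.0, 0.01)
        tr = sm.integrate_curve(spec)
        assert np.max(np.abs(wrap_difference(tr.theta - 0.5 * tr.t))) < 1e-8

    def test_constant_jerk_quadrature(self):
        spec = sm.CurveSpec((0,) * 5, (2.0, 0, 0), kp(v=1.0, a=0.5), 1.0, 0.01)
        tr = sm.integrate_curve(spec)
        np.testing.assert_allclose(tr.v, 1.0 + 0.5 * tr.t + tr.t**2, atol=1e-8)

    def test_straight_uniform_motion(self):
        spec = sm.CurveSpec((0,) * 5, (0, 0, 0), kp(x=2.0, y=-1.0), 1.0, 0.01)
        tr = sm.integrate_curve(spec)
        np.testing.assert_allclose(tr.x, 2.0 + tr.t, atol=1e-10)
        np.testing.assert_allclose(tr.y, -1.0, atol=1e-12)

    def test_matches_adaptive_reference(self, rng):
        ks = tuple(rng.uniform(-1, 1, 5))
        js = tuple(rng.uniform(-1, 1, 3))
        spec = sm.CurveSpec(ks, js, kp(x=0.1, y=-0.2, theta=0.3, v=1.2, a=0.1),
                            0.5, 0.005, span="forward")
        tr = sm.integrate_curve(spec)

        def rhs(t, s):
            _, x, y, th, v, a = s
            return [1, v * np.cos(th), v * np.sin(th),
                    spec.theta_dot(t), a, spec.a_dot(t)]

        sol = solve_ivp(rhs, [0, tr.t[-1]], spec.eta0.as_array(),
                        t_eval=tr.t, rtol=1e-12, atol=1e-13)
        ref = sol.y.T.copy()
        ref[:, 3] %= 2 * np.pi
        assert np.max(np.abs(tr.data - ref)) < 1e-6

    def test_local_truncation_order(self, rng):
        # one step of the integrator converges like a 4th-order scheme
        ks = tuple(rng.uniform(-1, 1, 5))
        js = tuple(rng.uniform(-1, 1, 3))
        eta0 = kp(theta=0.7, v=1.1, a=0.4)

        def one_step_error(h):
            spec = sm.CurveSpec(ks, js, eta0, 10 * h, h, span="forward")
            tr = sm.integrate_curve(spec)

            def rhs(t, s):
                _, x, y, th, v, a = s
                return [1, v * np.cos(th), v * np.sin(th),
                        spec.theta_dot(t), a, spec.a_dot(t)]

            sol = solve_ivp(rhs, [0, h], eta0.as_array(), rtol=1e-13, atol=1e-14)
            return np.max(np.abs(tr.data[1] - sol.y[:, -1]))

        e1, e2 = one_step_error(0.02), one_step_error(0.01)
        assert e1 / e2 > 16  # at least O(h^5) local error

    def test_horizontality_one_forms(self, rng):
        # the discrete tangent annihilates the defining 1-forms at O(dt^2)
        ks = tuple(rng.uniform(-1, 1, 5))
        js = tuple(rng.uniform(-1, 1, 3))

        def residual(dt):
            spec = sm.CurveSpec(ks, js, kp(v=1.0, a=0.2), 0.4, dt,
                                span="forward")
            tr = sm.integrate_curve(spec)
            dx, dy = np.diff(tr.x), np.diff(tr.y)
            dv, dtt = np.diff(tr.v), np.diff(tr.t)
            th, v, a = tr.theta[:-1], tr.v[:-1], tr.a[:-1]
            w1 = np.cos(th) * dx + np.sin(th) * dy - v * dtt
            w2 = -np.sin(th) * dx + np.cos(th) * dy
            w3 = dv - a * dtt
            return max(np.max(np.abs(w1)), np.max(np.abs(w2)), np.max(np.abs(w3)))

        r1, r2 = residual(0.02), residual(0.01)
        assert r1 / r2 > 3  # quadratic decay

    def test_step_too_large_rejected(self):
        with pytest.raises(ValueError, match="step"):
            sm.CurveSpec((0,) * 5, (0, 0, 0), kp(), horizon=0.1, step=0.02)

    def test_spec_roundtrip(self):
        spec = sm.CurveSpec((1, 2, 3, 4, 5), (6, 7, 8), kp(v=2.0), 0.5, 0.01)
        assert sm.CurveSpec.from_dict(spec.to_dict()) == spec


class TestFan:
    def test_curves_meet_at_common_point(self, rng):
        eta0 = kp(v=1.4)
        specs = [sm.CurveSpec(tuple(rng.uniform(-3, 3, 5)),
                              tuple(rng.uniform(-50, 50, 3)),
                              eta0, 0.07, 0.002) for _ in range(30)]
        fan = sm.generate_fan(specs)
        for tr in fan:
            mid = len(tr) // 2
            assert abs(tr.t[mid]) < 1e-12
            assert abs(tr.x[mid]) < 1e-9 and abs(tr.y[mid]) < 1e-9
            assert abs(tr.theta[mid]) < 1e-9

    def test_bell_matched_jerk_gives_bell_speed(self):
        prof = sm.BellProfile()
        # q = da/dt of the quartic bell; a(0) = 0, v(0) = v0
        q = (-4 * prof.v0 / prof.T**2, 0.0, 12 * prof.v0 / prof.T**4)
        eta0 = kp(v=prof.v0, a=0.0)
        specs = [sm.CurveSpec((k0, 0, 0, 0, 0), q, eta0, prof.T, prof.T / 20)
                 for k0 in np.linspace(-3, 3, 7)]
        for tr in sm.generate_fan(specs):
            np.testing.assert_allclose(tr.v, sm.bell_velocity(tr.t, prof),
                                       atol=1e-6)
            assert np.argmax(tr.v) == len(tr) // 2

    def test_singleton_fan_is_integrate_curve(self):
        spec = sm.CurveSpec((1, 0, 0, 0, 0), (0, 0, 0), kp(), 0.5, 0.01)
        fan = sm.generate_fan([spec])
        np.testing.assert_array_equal(fan[0].data,
                                      sm.integrate_curve(spec).data)

    def test_mismatched_initial_points_rejected(self):
        s1 = sm.CurveSpec((0,) * 5, (0, 0, 0), kp(v=1.0), 0.5, 0.01)
        s2 = sm.CurveSpec((0,) * 5, (0, 0, 0), kp(v=2.0), 0.5, 0.01)
        with pytest.raises(ValueError, match="eta0"):
            sm.generate_fan([s1, s2])


class TestCurveFamily:
    def test_twelve_free_parameters(self):
        params = sm.curve_family_parameters()
        assert len(params) == 12
        assert len(set(params)) == 12


class TestTrajectory:
    def test_rejects_non_monotone_time(self):
        data = np.zeros((5, 6))
        data[:, 0] = [0, 1, 2, 1.5, 3]
        with pytest.raises(ValueError, match="increasing"):
            sm.Trajectory(data)

    def test_rejects_non_uniform_step(self):
        data = np.zeros((4, 6))
        data[:, 0] = [0, 1, 2, 4]
        with pytest.raises(ValueError, match="uniform"):
            sm.Trajectory(data)

    def test_theta_wrapped_on_storage(self):
        data = np.zeros((3, 6))
        data[:, 0] = [0, 1, 2]
        data[:, 3] = [-0.1, 2 * np.pi + 0.2, 7.0]
        tr = sm.Trajectory(data)
        assert np.all((tr.theta >= 0) & (tr.theta < 2 * np.pi))
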