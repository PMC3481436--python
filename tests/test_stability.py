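import numpy as np
import pytest

import mimacro as mm
from mimacro.model import rhs_saturated


class TestLyapunovFunction:
    @pytest.mark.parametrize("state,expected", [
        ((0, 0, 0, 0, 0, 0), 0.0),
        ((1, 1, 1, 1, 1, 1), 3.0),
        ((3, 4, 0, 0, 0, 0), 12.5),
    ])
    def test_values(self, state, expected):
        assert mm.lyapunov_value(state) == pytest.approx(expected)

    def test_derivative_zero_at_origin(self, default_p):
        assert mm.lyapunov_derivative(np.zeros(6), default_p) == 0.0

    def test_derivative_negative_on_random_orthant_states(self, default_p):
        """Zero-input homeostasis: V decreases everywhere off the origin."""
        rng = np.random.default_rng(3)
        for _ in range(200):
            x = rng.uniform(0, 1, 6) * np.array([5e3, 5e3, 5e3, 20, 20, 20])
            if np.all(x == 0):
                continue
            assert mm.lyapunov_derivative(x, default_p) < 0.0

    def test_derivative_matches_finite_difference_along_trajectory(
            self, default_p, zero_inputs):
        """V-dot from the vector field agrees with a fourth-order central
        difference of V(t) along a tightly integrated zero-input
        trajectory, once the fast cytokine transient (rates up to 55/day)
        has passed."""
        s0 = mm.ModelState(1000, 400, 300, 2, 1, 3)
        traj = mm.integrate(s0, default_p, zero_inputs, (0.0, 5.0),
                            rtol=1e-11, samples_per_day=200)
        v = 0.5 * np.sum(traj.states ** 2, axis=1)
        dt = traj.times[1] - traj.times[0]
        # 4th-order central difference
        fd = (-v[4:] + 8 * v[3:-1] - 8 * v[1:-3] + v[:-4]) / (12 * dt)
        v_dot = np.array([mm.lyapunov_derivative(x, default_p)
                          for x in traj.states[2:-2]])
        # skip the first day: fast modes make any fixed-step stencil stiff
        start = int(1.0 / dt)
        rel = np.abs(fd[start:] - v_dot[start:]) / np.abs(v_dot[start:])
        assert np.max(rel) < 1e-6


class TestQuadraticBound:
    def test_default_certificate_is_globally_stable(self, default_p):
        cert = mm.quadratic_bound(default_p)
        assert cert.verdict == "globally_stable"
        assert np.all(cert.eigenvalues < 0)

    def test_matrix_is_symmetric_and_matches_printed_entries(self, default_p):
        q = mm.quadratic_bound(default_p).bound_matrix
        assert np.allclose(q, q.T)
        assert q[4, 4] == -55.0
        assert q[0, 1] == pytest.approx(1.1 / 2)

    def test_pathological_params_are_indeterminate(self, default_p):
        p = default_p.with_updates(k2=500.0, k3=500.0, d_il10=1e-6,
                                   d_ta=1e-6, d_il1=1e-6)
        assert mm.quadratic_bound(p).verdict == "indeterminate"

    def test_quadratic_form_equals_saturated_system_derivative(self, default_p):
        """x'Qx is exactly the Lyapunov derivative of the bilinear system
        obtained by saturating every Hill factor at 1 (independent oracle)."""
        q = mm.quadratic_bound(default_p).bound_matrix
        rng = np.random.default_rng(11)
        for _ in range(50):
            x = rng.uniform(0, 1e3, 6)
            assert x @ q @ x == pytest.approx(
                float(x @ rhs_saturated(x, default_p)), rel=1e-10)

    def test_bound_depends_only_on_params(self, default_p):
        a = mm.quadratic_bound(default_p)
        b = mm.quadratic_bound(default_p)
        assert np.array_equal(a.bound_matrix, b.bound_matrix)


class TestSosCheck:
    def test_printed_decomposition_slack_table(self, default_p):
        """Frozen hand arithmetic on the printed completed-square form:
        x1^2 balances exactly, x1x2 within rounding, and the x3^2 budget is
        overdrawn by 0.125 (0.05 + 0.3*0.25 + 0.25 = 0.375 against 0.25)."""
        rep = mm.sos_decomposition_check(default_p)
        assert rep["x1^2"]["sos"] == pytest.approx(0.02 + 1.28 + 0.30)
        assert rep["x1^2"]["slack"] == pytest.approx(0.0, abs=1e-12)
        assert rep["x1x2"]["sos"] == pytest.approx(2 * 1.28 * 0.429)
        assert abs(rep["x1x2"]["slack"]) < 0.01
        assert rep["x3^2"]["sos"] == pytest.approx(0.375)
        assert rep["x3^2"]["slack"] == pytest.approx(-0.125)
        # every other monomial balances within the printed rounding
        for key, row in rep.items():
            if key != "x3^2":
                assert abs(row["slack"]) < 0.01


class TestPointwiseDomination:
    def test_equality_at_origin(self, default_p):
        x = np.zeros(6)
        q = mm.quadratic_bound(default_p).bound_matrix
        assert mm.lyapunov_derivative(x, default_p) == float(x @ q @ x) == 0.0

    def test_domination_holds_when_unactivated_pool_is_empty(self, default_p):
        """With x1 = 0 the saturated form only inflates destabilizing cross
        terms, so it genuinely dominates the true derivative there."""
        q = mm.quadratic_bound(default_p).bound_matrix
        rng = np.random.default_rng(5)
        for _ in range(200):
            x = rng.uniform(0, 1, 6) * np.array([0, 5e3, 5e3, 20, 20, 20])
            assert mm.lyapunov_derivative(x, default_p) <= float(x @ q @ x) + 1e-9

    def test_known_counterexample_is_detected(self, default_p):
        """At x = (1,0,0,0,0,0) the true derivative is -mu while the
        saturated form is -(mu+k2+k3+k4): the claimed orthant-wide
        domination fails and the checker must report it."""
        q = mm.quadratic_bound(default_p).bound_matrix
        x = np.array([1.0, 0, 0, 0, 0, 0])
        vdot = mm.lyapunov_derivative(x, default_p)
        assert vdot == pytest.approx(-0.2)
        assert float(x @ q @ x) == pytest.approx(-1.6)
        assert vdot > float(x @ q @ x)
        report = mm.pointwise_bound_dominates(default_p, n_samples=500, seed=1)
        assert report["n_violations"] > 0
        assert not report["dominates"]
        assert report["worst_gap"] > 0

    def test_near_equality_under_cytokine_saturation(self, default_p):
        """When every cytokine vastly exceeds its Hill constant the true
        derivative approaches the saturated quadratic form."""
        p = default_p  # Hill constants 1.0
        q = mm.quadratic_bound(p).bound_matrix
        x = np.array([10.0, 20.0, 15.0, 1e7, 1e7, 1e7])
        vdot = mm.lyapunov_derivative(x, p)
        qform = float(x @ q @ x)
        assert vdot <= qform + 1e-6
        # activation/secretion terms agree to the saturation error ~c/x
        assert vdot == pytest.approx(qform, rel=1e-4)

    def test_report_is_deterministic_for_fixed_seed(self, default_p):
        a = mm.pointwise_bound_dominates(default_p, n_samples=200, seed=9)
        b = mm.pointwise_bound_dominates(default_p, n_samples=200, seed=9)
        assert a == b
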