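"""Solver correctness, the weighted quadratic loss, and solver gradients."""

import numpy as np
import pytest

from nodefit import models, trajectory
from nodefit.series import SmoothedSeries
from nodefit.trajectory import SolverConfig, Trajectory, weighted_loss


def _linear_pv(S, b=None):
    """ODE-family vector with identity activation: du/dt = S u - b."""
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    b = np.zeros(n) if b is None else np.asarray(b, dtype=float)
    spec = models.ModelSpec("ode", n=n, n_obs=n, activation="identity")
    return models.ParameterVector(spec, np.concatenate([S.ravel(), b]))


class TestSolve:
    def test_zero_field_constant_trajectory(self):
        spec = models.ModelSpec("ode", n=2, n_obs=2)
        pv = models.ParameterVector(spec, np.zeros(6))
        u0 = np.array([1.5, -0.5])
        traj = trajectory.solve(pv, u0, np.linspace(0, 10, 11))
        np.testing.assert_allclose(traj.states, np.tile(u0, (11, 1)), atol=1e-9)

    @pytest.mark.parametrize("method", ["Radau", "BDF", "LSODA", "RK45"])
    def test_exponential_decay_closed_form(self, method):
        pv = _linear_pv([[-1.0]])
        cfg = SolverConfig(method=method, rtol=1e-8, atol=1e-10)
        times = np.linspace(0, 5, 26)
        traj = trajectory.solve(pv, np.array([1.0]), times, cfg)
        np.testing.assert_allclose(traj.states[:, 0], np.exp(-times), atol=1e-6)

    def test_harmonic_oscillator_closed_form(self):
        # du1/dt = u2, du2/dt = -u1, u0 = (1, 0) -> (cos t, -sin t)
        pv = _linear_pv([[0.0, 1.0], [-1.0, 0.0]])
        times = np.linspace(0, 20, 101)
        cfg = SolverConfig(method="Radau", rtol=1e-9, atol=1e-11)
        traj = trajectory.solve(pv, np.array([1.0, 0.0]), times, cfg)
        np.testing.assert_allclose(traj.states[:, 0], np.cos(times), atol=1e-6)
        np.testing.assert_allclose(traj.states[:, 1], -np.sin(times), atol=1e-6)

    def test_family_default_methods(self):
        assert trajectory.default_method(models.ModelSpec("ode", n=2)) == "Radau"
        assert trajectory.default_method(models.ModelSpec("node", n=2)) == "BDF"

    def test_failure_carries_parameter_snapshot(self):
        # exploding linear system overflows before reaching the horizon
        pv = _linear_pv([[50.0]])
        with pytest.raises(trajectory.IntegrationError) as err:
            trajectory.solve(
                pv, np.array([1.0]), np.linspace(0, 50, 11),
                SolverConfig(method="RK45", max_steps=100),
            )
        assert err.value.params is not None


class TestWeightedLoss:
    def _pair(self, T=5, V=2):
        times = np.arange(float(T))
        target = SmoothedSeries(times, np.zeros((T, V)), [f"v{i}" for i in range(V)])
        traj = Trajectory(times, np.zeros((T, V)))
        return traj, target

    def test_zero_when_trajectory_matches_target(self):
        traj, target = self._pair()
        assert weighted_loss(traj, target) == 0.0

    def test_single_weighted_deviation(self):
        traj, target = self._pair()
        traj.states[3, 1] = 2.0
        w = np.full(5, 0.25)
        assert weighted_loss(traj, target, w) == pytest.approx(0.25 * 4.0)

    def test_all_ones_weights_equal_unweighted(self):
        rng = np.random.default_rng(0)
        traj, target = self._pair(T=181, V=2)
        traj.states[...] = rng.normal(size=(181, 2))
        assert weighted_loss(traj, target, np.ones(181)) == pytest.approx(
            weighted_loss(traj, target)
        )

    def test_362_components_on_the_standard_grid(self):
        # 181 half-yearly points x 2 species; unit deviations count 362
        traj, target = self._pair(T=181, V=2)
        traj.states[...] = 1.0
        assert weighted_loss(traj, target) == pytest.approx(362.0)

    def test_dummy_dimensions_never_compared(self):
        times = np.arange(4.0)
        target = SmoothedSeries(times, np.zeros((4, 2)), ["a", "b"])
        traj = Trajectory(times, np.column_stack([np.zeros((4, 2)), np.full(4, 9.9)]))
        assert weighted_loss(traj, target, n_obs=2) == 0.0

    def test_grid_mismatch_rejected(self):
        traj, target = self._pair()
        traj.times = traj.times + 0.5
        with pytest.raises(ValueError, match="grid"):
            weighted_loss(traj, target)


class TestLossGradient:
    def _target_from(self, pv, u0, times, shift=0.0):
        cfg = SolverConfig(method="LSODA", rtol=1e-10, atol=1e-12)
        traj = trajectory.solve(pv, u0, times, cfg)
        names = [f"v{i}" for i in range(pv.spec.n)]
        return SmoothedSeries(times, traj.states[:, : pv.spec.n_obs] + shift,
                              names[: pv.spec.n_obs])

    def test_zero_loss_and_gradient_at_global_minimum(self):
        spec = models.ModelSpec("ode", n=2, n_obs=2)
        pv = models.ParameterVector(spec, np.array([0.0, 0.8, -0.8, 0.0, 0.1, -0.1]))
        times = np.linspace(0, 6, 13)
        u0 = np.array([0.4, 0.0])
        target = self._target_from(pv, u0, times)
        loss, g = trajectory.loss_and_gradient(pv, u0, target, cfg=SolverConfig(method="LSODA"))
        assert loss < 1e-10
        assert np.linalg.norm(g) < 1e-4

    def test_forward_sensitivity_matches_closed_form_linear_system(self):
        # du/dt = s*u, u0=1: dL/ds for L = sum (u(t) - y_t)^2 has the exact
        # form sum 2 (e^{st} - y_t) t e^{st}
        s = -0.7
        pv = _linear_pv([[s]])
        times = np.linspace(0, 3, 7)
        y = np.exp(s * times) + 0.3
        target = SmoothedSeries(times, y[:, None], ["u"])
        loss, g = trajectory.loss_and_gradient(
            pv, np.array([1.0]), target,
            cfg=SolverConfig(method="LSODA", rtol=1e-10, atol=1e-12),
        )
        u = np.exp(s * times)
        expected_dLds = np.sum(2 * (u - y) * times * u)
        np.testing.assert_allclose(g[0], expected_dLds, rtol=1e-6)
        # b and the off-pattern entries exist too: flat = [S00, b0]
        assert g.shape == (2,)

    @pytest.mark.parametrize(
        "spec",
        [
            models.ModelSpec("ode", n=2, n_obs=2),
            models.ModelSpec("node", n=2, n_obs=2, N=3),
        ],
        ids=["ode", "node"],
    )
    def test_gradient_matches_central_finite_differences(self, spec):
        rng = np.random.default_rng(7)
        pv = models.ParameterVector(
            spec, rng.normal(0, 0.4, models.count_parameters(spec))
        )
        times = np.linspace(0, 4, 9)
        u0 = np.array([0.3, -0.2])
        target = self._target_from(pv, u0, times, shift=0.15)
        w = np.linspace(0.2, 1.0, times.size)
        cfg = SolverConfig(method="LSODA", rtol=1e-9, atol=1e-11)
        loss, g = trajectory.loss_and_gradient(pv, u0, target, w, cfg)
        assert loss > 0
        h = 1e-5
        tight = SolverConfig(method="LSODA", rtol=1e-11, atol=1e-13)
        for j in range(pv.flat.size):
            fp, fm = pv.flat.copy(), pv.flat.copy()
            fp[j] += h
            fm[j] -= h
            lp = weighted_loss(
                trajectory.solve(models.ParameterVector(spec, fp), u0, times, tight),
                target, w, n_obs=2,
            )
            lm = weighted_loss(
                trajectory.solve(models.ParameterVector(spec, fm), u0, times, tight),
                target, w, n_obs=2,
            )
            fd = (lp - lm) / (2 * h)
            assert abs(g[j] - fd) <= 1e-4 * max(abs(fd), 1e-3), f"param {j}"
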