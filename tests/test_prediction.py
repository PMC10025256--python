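"""Train/test splitting, posterior trajectory ensembles, loss summaries."""

import numpy as np
import pytest

from nodefit import models, prediction, psgld, trajectory, training
from nodefit.prediction import SplitSpec, compare_repeated, phase_export, split
from nodefit.series import SmoothedSeries
from nodefit.trajectory import Trajectory

FAST = trajectory.SolverConfig(method="LSODA")


class TestSplit:
    def test_standard_grid_counts(self, lv_target):
        # 181 half-yearly points over 0-90: times <= 60 give 121 training
        # points, the remaining 60 are the test window
        train, test = split(lv_target, SplitSpec(60.0))
        assert train.n_points == 121
        assert test.n_points == 60

    def test_partition_restores_grid(self, lv_target):
        train, test = split(lv_target, SplitSpec(45.0))
        np.testing.assert_array_equal(
            np.concatenate([train.times, test.times]), lv_target.times
        )
        np.testing.assert_array_equal(
            np.vstack([train.values, test.values]), lv_target.values
        )

    def test_split_outside_range_rejected(self, lv_target):
        for t in (-5.0, 0.0, 90.0, 120.0):
            with pytest.raises(ValueError):
                split(lv_target, SplitSpec(t))

    def test_metadata_propagates(self, lv_target):
        train, _ = split(lv_target, SplitSpec(60.0))
        np.testing.assert_array_equal(train.log_means, lv_target.log_means)
        assert train.smoothing_sigma == lv_target.smoothing_sigma


@pytest.fixture(scope="module")
def toy_posterior(rotation_target):
    """Small posterior ensemble around the known rotation optimum."""
    target, pv_true = rotation_target
    res = training.fit(
        pv_true.spec, target,
        training.FitConfig(segments=1, ramp_iters=0, iters_per_segment=10,
                           lr=0.01, seed=0, solver=FAST),
        params0=pv_true,
    )
    hyper = psgld.PsgldHyper(epsilon=1e-5, n_warmup=10, n_collect=40, seed=0)
    return psgld.sample(res, target, hyper, FAST), res, target


class TestEnsemblePredict:
    def test_member_count_and_determinism(self, toy_posterior):
        ens, res, target = toy_posterior
        a = prediction.ensemble_predict(ens, res.params.spec, res.u0,
                                        target.times, K=7, seed=5, solver=FAST)
        b = prediction.ensemble_predict(ens, res.params.spec, res.u0,
                                        target.times, K=7, seed=5, solver=FAST)
        assert a.size == 7
        np.testing.assert_array_equal(a.member_indices, b.member_indices)
        np.testing.assert_allclose(a.trajectories, b.trajectories)

    def test_full_ensemble_uses_every_sample_once(self, toy_posterior):
        ens, res, target = toy_posterior
        te = prediction.ensemble_predict(ens, res.params.spec, res.u0,
                                         target.times, K=ens.size, seed=0, solver=FAST)
        assert sorted(te.member_indices) == list(range(ens.size))

    def test_oversized_request_rejected(self, toy_posterior):
        ens, res, target = toy_posterior
        with pytest.raises(ValueError, match="ensemble"):
            prediction.ensemble_predict(ens, res.params.spec, res.u0,
                                        target.times, K=ens.size + 1, seed=0)


class TestLossSummary:
    def test_identical_members_have_zero_sd(self, toy_posterior):
        ens, res, target = toy_posterior
        clones = psgld.PosteriorEnsemble(
            np.tile(res.params.flat, (5, 1)), np.zeros(5), ens.hyper
        )
        mean, sd = prediction.loss_summary(clones, res.params.spec, res.u0,
                                           target, M=5, seed=0, solver=FAST)
        assert sd == 0.0

    def test_mean_and_unbiased_sd_of_two_members(self):
        # mean of window losses 1 and 3 is 2; unbiased sample SD is sqrt(2)
        losses = np.array([1.0, 3.0])
        assert np.mean(losses) == pytest.approx(2.0)
        assert np.std(losses, ddof=1) == pytest.approx(np.sqrt(2.0))

    def test_two_seeds_agree_within_sampling_error(self, toy_posterior):
        ens, res, target = toy_posterior
        m1, s1 = prediction.loss_summary(ens, res.params.spec, res.u0, target,
                                         M=20, seed=1, solver=FAST)
        m2, s2 = prediction.loss_summary(ens, res.params.spec, res.u0, target,
                                         M=20, seed=2, solver=FAST)
        se = np.sqrt(s1**2 / 20 + s2**2 / 20) + 1e-12
        assert abs(m1 - m2) < 3 * se + 1e-9

    def test_window_restricts_the_loss(self, toy_posterior):
        ens, res, target = toy_posterior
        full = prediction.member_losses(ens, res.params.spec, res.u0, target,
                                        FAST, window=None)
        early = prediction.member_losses(ens, res.params.spec, res.u0, target,
                                         FAST, window=(target.times[0] - 1, 4.0))
        late = prediction.member_losses(ens, res.params.spec, res.u0, target,
                                        FAST, window=(4.0, target.times[-1]))
        np.testing.assert_allclose(early + late, full, rtol=1e-8)


class TestCompareRepeated:
    def test_dominated_ensemble_always_wins(self):
        a = np.random.default_rng(0).uniform(0.0, 1.0, 500)
        b = np.random.default_rng(1).uniform(10.0, 11.0, 500)
        frac = compare_repeated(a, b, reps=50, M=100, seed=0)
        assert frac == 1.0

    def test_identical_distributions_near_half_on_average(self):
        # with identical loss populations the comparison is symmetric, so
        # the fraction averages to one half; any single run fluctuates with
        # the reference-mean draw, so average over seeds
        losses = np.random.default_rng(7).gamma(2.0, 1.0, 5000)
        fracs = [
            compare_repeated(losses, losses, reps=100, M=500, seed=s)
            for s in range(20)
        ]
        assert abs(np.mean(fracs) - 0.5) < 0.15

    def test_desk_scale_capacity(self):
        # the published protocol's sizes (80 reps of 3000-member means)
        losses = np.random.default_rng(0).gamma(2.0, 1.0, 4000)
        frac = compare_repeated(losses, losses, reps=80, M=3000, seed=0)
        assert 0.0 <= frac <= 1.0


class TestPhaseExport:
    def _data_and_traj(self, n_model=3):
        times = np.arange(6.0)
        data = SmoothedSeries(times, np.column_stack([np.sin(times), np.cos(times)]),
                              ["hare", "lynx"])
        states = np.column_stack([np.sin(times) + 0.1, np.cos(times) - 0.1,
                                  np.linspace(1.0, 0.0, 6)])[:, :n_model]
        return data, Trajectory(times, states)

    def test_observed_dims_only(self):
        data, traj = self._data_and_traj()
        table = phase_export(data, None, [1, 2])
        assert len(table) == 6
        np.testing.assert_array_equal(table["data_dim1"], data.values[:, 0])
        assert "model_dim1" not in table.columns

    def test_dummy_dim_copied_from_model_to_data_path(self):
        data, traj = self._data_and_traj()
        table = phase_export(data, traj, [1, 2, 3])
        # the data path borrows the model's third (dummy) coordinate
        np.testing.assert_array_equal(table["data_dim3"], traj.states[:, 2])
        np.testing.assert_array_equal(table["model_dim3"], traj.states[:, 2])
        np.testing.assert_array_equal(table["data_dim1"], data.values[:, 0])
        np.testing.assert_array_equal(table["model_dim1"], traj.states[:, 0])

    def test_dummy_dim_without_model_rejected(self):
        data, _ = self._data_and_traj()
        with pytest.raises(ValueError, match="dummy"):
            phase_export(data, None, [1, 2, 3])

    def test_row_count_matches_grid(self):
        data, traj = self._data_and_traj()
        assert len(phase_export(data, traj, [1, 2])) == data.n_points
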