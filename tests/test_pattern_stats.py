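"""Trajectory statistics, persistence times, correlations and group contrasts."""

import numpy as np
import pytest

from spinocc import (
    SpinGlassModel,
    TrajectoryEnsemble,
    group_contrast,
    occupancy_trajectory,
    parameter_observable_correlation,
    persistence_distribution,
)
from spinocc.occupancy_data import MomentSet
from spinocc.pattern_stats import log_binned


def _ensemble(trials):
    return TrajectoryEnsemble(np.asarray(trials, dtype=np.uint8))


class TestOccupancyTrajectory:
    def test_all_zero_signal(self):
        stats = occupancy_trajectory(_ensemble(np.zeros((3, 10, 4))))
        np.testing.assert_array_equal(stats.mean_curve, 0.0)
        np.testing.assert_array_equal(stats.sd_curve, 0.0)
        np.testing.assert_array_equal(stats.per_node_stationary, 0.0)

    def test_single_trial_zero_sd(self, rng):
        stats = occupancy_trajectory(_ensemble(rng.integers(0, 2, (1, 20, 3))))
        np.testing.assert_array_equal(stats.sd_curve, 0.0)

    def test_two_trial_hand_values(self):
        # node-averages 0.4 and 0.6 at every step (5 nodes, 2 resp. 3 occupied)
        t1 = np.tile([1, 1, 0, 0, 0], (6, 1))
        t2 = np.tile([1, 1, 1, 0, 0], (6, 1))
        stats = occupancy_trajectory(_ensemble([t1, t2]))
        np.testing.assert_allclose(stats.mean_curve, 0.5)
        np.testing.assert_allclose(stats.sd_curve, 0.1)  # population convention
        np.testing.assert_allclose(stats.daily_means, [0.4, 0.6])

    def test_stationary_window_selection(self):
        tr = np.zeros((2, 10, 2), dtype=np.uint8)
        tr[:, 5:, :] = 1
        stats = occupancy_trajectory(_ensemble(tr), stationary=(5, 10))
        np.testing.assert_array_equal(stats.per_node_stationary, 1.0)


class TestPersistence:
    def test_boundary_censoring_rule(self):
        series = np.array([[0, 0, 1, 1, 1, 0]]).T[None, :, :]  # 1 trial, 1 node
        dist = persistence_distribution(series)
        np.testing.assert_array_equal(dist.taus, [3.0])
        np.testing.assert_array_equal(dist.probs, [1.0])
        assert dist.censoring_policy["n_completed"] == 1
        assert dist.censoring_policy["n_censored"] == 2
        assert dist.censoring_policy["total_frames"] == 6

    def test_alternating_signal_all_tau_one(self):
        series = np.array([[0, 1, 0, 1, 0, 1]]).T[None, :, :]
        dist = persistence_distribution(series)
        np.testing.assert_array_equal(dist.taus, [1.0])
        np.testing.assert_array_equal(dist.probs, [1.0])

    def test_constant_series_fully_censored(self):
        series = np.ones((1, 8, 1), dtype=np.uint8)
        dist = persistence_distribution(series)
        assert dist.taus.size == 0
        assert dist.censoring_policy["total_frames"] == 8

    def test_keep_boundary_runs_option(self):
        series = np.array([[0, 0, 1, 1, 1, 0]]).T[None, :, :]
        dist = persistence_distribution(series, censor_boundaries=False)
        np.testing.assert_array_equal(dist.taus, [1.0, 2.0, 3.0])
        np.testing.assert_allclose(dist.probs, [1 / 3, 1 / 3, 1 / 3])

    def test_markov_switching_gives_geometric_law(self, rng):
        # two-state chain, switch probability q: tau ~ Geometric(q), mean 1/q
        q, n = 0.2, 200_000
        flips = rng.random(n) < q
        series = (np.cumsum(flips) % 2).astype(np.uint8)[None, :, None]
        dist = persistence_distribution(series)
        assert dist.mean_tau == pytest.approx(1 / q, rel=0.05)
        # P(tau) ratio between consecutive taus approximates 1 - q
        ratios = dist.probs[1:6] / dist.probs[:5]
        np.testing.assert_allclose(ratios, 1 - q, atol=0.05)

    def test_total_time_conservation(self, rng):
        arr = rng.integers(0, 2, size=(3, 50, 2)).astype(np.uint8)
        dist = persistence_distribution(arr)
        assert dist.censoring_policy["total_frames"] == 3 * 50 * 2

    def test_log_binning_preserves_mass(self, rng):
        arr = rng.integers(0, 2, size=(2, 500, 3)).astype(np.uint8)
        dist = persistence_distribution(arr)
        lb = log_binned(dist)
        assert lb.probs.sum() == pytest.approx(1.0)


class TestParameterObservableCorrelation:
    def _model_and_moments(self, h, occ_means, occ_pairs):
        n = len(h)
        model = SpinGlassModel(np.asarray(h, dtype=float), np.zeros((n, n)))
        spin_means = 2 * np.asarray(occ_means) - 1
        pairs = np.asarray(occ_pairs)
        i, j = np.triu_indices(n, 1)
        spin_pairs = 4 * pairs - 2 * np.asarray(occ_means)[i] - 2 * np.asarray(occ_means)[j] + 1
        m = MomentSet(spin_means, spin_pairs, np.asarray(occ_means), pairs)
        return model, m

    def test_identical_vectors_unit_correlation(self):
        model, m = self._model_and_moments(
            [0.1, 0.2, 0.3], [0.1, 0.2, 0.3], [0.02, 0.03, 0.06])
        r = parameter_observable_correlation(model, m, "h-vs-occupancy")
        assert r.statistic == pytest.approx(1.0)

    def test_negated_vectors(self):
        model, m = self._model_and_moments(
            [-0.1, -0.2, -0.3], [0.1, 0.2, 0.3], [0.02, 0.03, 0.06])
        r = parameter_observable_correlation(model, m, "h-vs-occupancy")
        assert r.statistic == pytest.approx(-1.0)

    def test_monotone_atanh_map_nearly_linear(self):
        # independent-nodes fields h = atanh(2p - 1) against occupancy p:
        # a monotone, mildly nonlinear map, so Pearson r stays above 0.99
        p = np.linspace(0.27, 0.73, 8)  # |h| <= 1
        h = np.arctanh(2 * p - 1)
        n = p.size
        i, j = np.triu_indices(n, 1)
        model = SpinGlassModel(h, np.zeros((n, n)))
        m = MomentSet.from_spin(2 * p - 1, (2 * p - 1)[i] * (2 * p - 1)[j])
        r = parameter_observable_correlation(model, m, "h-vs-occupancy")
        assert r.statistic > 0.99

    def test_zero_variance_rejected(self):
        model, m = self._model_and_moments(
            [0.5, 0.5, 0.5], [0.1, 0.2, 0.3], [0.02, 0.03, 0.06])
        with pytest.raises(ValueError, match="zero variance"):
            parameter_observable_correlation(model, m, "h-vs-occupancy")

    def test_pair_mode_dimensions(self, small_model):
        from spinocc import model_moments

        r = parameter_observable_correlation(
            small_model, model_moments(small_model), "J-vs-Cij")
        assert r.groups["n_points"] == 6
        assert -1 <= r.statistic <= 1


class TestRoundTripCorrelations:
    def test_fitted_parameters_track_observables(self):
        """Sample from a known 8-node model, fit, and correlate parameters
        with observables: h tracks <I_i> almost linearly (r > 0.95); J
        tracks the connected pair correlation C_ij - <I_i><I_j> (r > 0.8).
        The raw second moment <I_i I_j> is dominated by the mean products
        when fields vary widely, so only the connected part is diagnostic
        of the couplings in this regime."""
        from spinocc import (
            SyntheticSpec, empirical_moments, fit, make_ground_truth,
            pair_indices, sample_dataset,
        )

        spec = SyntheticSpec(n_nodes=8, seed=5, n_trials=1,
                             trial_length=100_000)
        truth = make_ground_truth(spec)
        sig = sample_dataset(truth, spec)
        m = empirical_moments(sig)
        res = fit(m)
        r_h = parameter_observable_correlation(res.model, m, "h-vs-occupancy")
        assert r_h.statistic > 0.95
        pairs = pair_indices(8)
        i = [p[0] for p in pairs]
        j = [p[1] for p in pairs]
        connected = m.occ_pairs - m.occ_means[i] * m.occ_means[j]
        r_j = np.corrcoef(res.model.J_upper, connected)[0, 1]
        assert r_j > 0.8


class TestGroupContrast:
    def test_identical_groups_zero_t(self):
        r = group_contrast([1, 2, 3, 1, 2, 3],
                           ["a", "a", "a", "b", "b", "b"])
        assert r.statistic == pytest.approx(0.0)

    def test_welch_toy_hand_value(self):
        # (1,2,3) vs (4,5,6): means 2 and 5, s^2 = 1 each, n = 3
        # t = (2 - 5) / sqrt(1/3 + 1/3) = -3.674235...
        r = group_contrast([1, 2, 3, 4, 5, 6],
                           ["a", "a", "a", "b", "b", "b"])
        expected = -3 / np.sqrt(2 / 3)
        assert r.statistic == pytest.approx(expected, abs=1e-12)
        assert r.groups == {"a": 3, "b": 3}

    def test_degenerate_variance_flagged(self):
        with pytest.raises(ValueError, match="degenerate"):
            group_contrast([0, 0, 1, 1], ["a", "a", "b", "b"])

    def test_identical_constant_groups(self):
        r = group_contrast([2, 2, 2, 2], ["a", "a", "b", "b"])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            group_contrast([1, 2, 3], ["a", "a", "a"])

    def test_anova_kind(self, rng):
        vals = rng.normal(size=12)
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        r = group_contrast(vals, labels, kind="anova")
        assert r.kind == "anova" and r.statistic >= 0
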