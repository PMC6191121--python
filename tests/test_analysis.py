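import itertools

import numpy as np
import pytest

from evint.analysis import (
    behavior_summary, elbow_select, fit_chronometric, fit_exponential,
    fit_psychometric, kmeans_cluster, psychophysical_kernel,
    time_to_fraction_max, unit_feature_matrix, unit_time_courses,
)
from evint.rl_environment import EpisodeRecord, Outcome


def make_record(n_steps, correct, noise=0.5, label=0, decision=None,
                hidden=None, obs=None, n_units=3, n_obs=4):
    if decision is None:
        decision = 1 if (correct == (label == 0)) else 2
    actions = np.zeros(n_steps, dtype=int)
    actions[-1] = decision
    outcome = Outcome.CORRECT if correct else Outcome.INCORRECT
    return EpisodeRecord(
        observations=np.zeros((n_steps, n_obs)) if obs is None else np.asarray(obs),
        actions=actions,
        pis=np.full((n_steps, 3), 1 / 3),
        rewards=np.zeros(n_steps),
        values=np.zeros(n_steps),
        hidden_policy=np.zeros((n_steps, n_units)) if hidden is None else np.asarray(hidden),
        hidden_value=np.zeros((n_steps, n_units)),
        label=label, noise_proportion=noise, outcome=outcome,
    )


class TestExponentialFit:
    def test_recovers_planted_parameters(self):
        t = np.arange(1, 11)
        y = -0.4 * np.exp(-0.7 * t) + 0.9
        fit = fit_exponential(t, y)
        assert abs(fit.B - (-0.7)) < 1e-4
        assert fit.residual < 1e-10

    def test_constant_data_fits_exactly(self):
        fit = fit_exponential(np.arange(1, 8), np.full(7, 0.6))
        assert fit.residual < 1e-8
        assert np.allclose(fit(np.arange(1, 8)), 0.6, atol=1e-4)

    def test_refit_of_fitted_curve_is_idempotent(self):
        t = np.arange(1, 11)
        fit = fit_exponential(t, -0.3 * np.exp(0.2 * t) + 1.1)
        refit = fit_exponential(t, fit(t))
        assert refit.residual < 1e-10

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential([1, 2, 3], [0.1, 0.2, 0.3])


class TestTimeToFractionMax:
    def test_reaches_ninety_percent_at_third_step(self):
        assert time_to_fraction_max([0.5, 0.8, 0.95, 0.96]) == 3

    def test_flat_sequence_reaches_immediately(self):
        assert time_to_fraction_max([0.9, 0.9, 0.9]) == 1

    def test_full_fraction_on_increasing_data_is_argmax(self):
        acc = [0.2, 0.5, 0.7, 0.99]
        assert time_to_fraction_max(acc, fraction=1.0) == 4

    def test_custom_time_axis(self):
        assert time_to_fraction_max([0.2, 0.9], times=[4, 7]) == 7

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            time_to_fraction_max([])


class TestBehaviorSummary:
    def test_all_correct_cell_flags_undefined_comparison(self):
        recs = [make_record(5, True) for _ in range(4)]
        s = behavior_summary(recs)
        assert s.accuracy.iloc[0] == 1.0
        assert s.mean_obs.iloc[0] == 5.0
        assert np.isnan(s.ranksum_p.iloc[0])

    def test_hand_computed_length_difference(self):
        recs = ([make_record(n, True) for n in (10, 12)]
                + [make_record(n, False) for n in (4, 6)])
        s = behavior_summary(recs)
        assert s.mean_len_correct.iloc[0] - s.mean_len_incorrect.iloc[0] == 6.0
        assert s.accuracy.iloc[0] == 0.5
        assert s.ranksum_p.notna().iloc[0]

    def test_histogram_mass_equals_trial_count(self):
        recs = [make_record(n, True) for n in (4, 4, 5, 9)]
        s = behavior_summary(recs)
        assert s.length_hist.iloc[0].sum() == 4

    def test_rebinned_histogram_normalized_per_level(self):
        recs = [make_record(n, True) for n in (4, 4, 5, 9, 14)]
        s = behavior_summary(recs, bin_width=6)
        hist = s.length_hist.iloc[0]
        assert hist.sum() == pytest.approx(1.0)   # 5 answered / 5 total
        assert len(hist) * 6 >= 15

    def test_answered_plus_unanswered_conserved(self):
        recs = [make_record(5, True) for _ in range(3)]
        timeout = make_record(50, True)
        timeout.outcome = Outcome.TIMEOUT
        s = behavior_summary(recs + [timeout])
        assert s.n_total.iloc[0] == 4
        assert s.n_answered.iloc[0] == 3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            behavior_summary([])


def test_psychometric_and_chronometric_fits_recover_trends():
    s = np.array([3, 6, 12, 25, 50, 100], dtype=float)
    acc = np.array([0.55, 0.62, 0.75, 0.9, 0.97, 0.99])
    (alpha, beta, lapse), f = fit_psychometric(s, acc)
    assert np.all(np.diff(f(s)) >= 0)
    assert abs(f(100) - 0.99) < 0.05
    (slope, intercept), res = fit_chronometric(s, 10 - 0.05 * s)
    assert slope == pytest.approx(-0.05)
    assert intercept == pytest.approx(10.0)


class TestUnitTimeCourses:
    def test_single_episode_returns_raw_traces(self):
        h = np.arange(12.0).reshape(4, 3)
        rec = make_record(4, True, hidden=h)
        courses = unit_time_courses([rec])
        assert np.allclose(courses[(0.5, 0)], h)

    def test_averaging_is_idempotent_for_identical_episodes(self):
        h = np.arange(12.0).reshape(4, 3)
        recs = [make_record(4, True, hidden=h) for _ in range(3)]
        assert np.allclose(unit_time_courses(recs)[(0.5, 0)], h)

    def test_known_condition_means_recovered(self):
        r1 = make_record(2, True, hidden=np.array([[0.0, 2], [2, 4]]), n_units=2)
        r2 = make_record(2, True, hidden=np.array([[2.0, 4], [4, 6]]), n_units=2)
        courses = unit_time_courses([r1, r2])
        assert np.allclose(courses[(0.5, 0)], [[1, 3], [3, 5]])

    def test_short_trials_excluded_from_late_steps(self):
        r1 = make_record(2, True, hidden=np.ones((2, 3)))
        r2 = make_record(4, True, hidden=2 * np.ones((4, 3)))
        c = unit_time_courses([r1, r2])[(0.5, 0)]
        assert np.allclose(c[0], 1.5)
        assert np.allclose(c[3], 2.0)

    def test_output_traces_available(self):
        rec = make_record(3, True)
        c = unit_time_courses([rec], which="pis")[(0.5, 0)]
        assert c.shape == (3, 3)


class TestKMeans:
    def test_k1_gives_grand_mean_and_total_ss(self, rng):
        X = rng.normal(size=(12, 4))
        res = kmeans_cluster(X, 1)
        assert np.allclose(res.centroids[0], X.mean(axis=0))
        assert res.d == pytest.approx(((X - X.mean(0)) ** 2).sum())

    def test_k_equals_n_gives_zero_distance(self, rng):
        X = rng.normal(size=(6, 3))
        res = kmeans_cluster(X, 6)
        assert res.d == pytest.approx(0.0, abs=1e-12)

    def test_planted_blobs_recovered_and_match_exhaustive_oracle(self, rng):
        centers = np.array([[0, 0], [10, 10], [-10, 10]], dtype=float)
        X = np.vstack([c + 0.1 * rng.normal(size=(3, 2)) for c in centers])
        res = kmeans_cluster(X, 3)
        planted = np.repeat(np.arange(3), 3)
        # same partition up to relabeling
        mapping = {}
        for a, p in zip(res.assignments, planted):
            mapping.setdefault(a, p)
            assert mapping[a] == p
        # exhaustive-assignment oracle over all partitions of 9 points into 3 labels
        best = np.inf
        for assign in itertools.product(range(3), repeat=9):
            if len(set(assign)) < 3:
                continue
            d = 0.0
            for k in range(3):
                pts = X[np.array(assign) == k]
                d += ((pts - pts.mean(axis=0)) ** 2).sum()
            best = min(best, d)
        assert res.d == pytest.approx(best, rel=1e-9)

    def test_d_non_increasing_in_k(self, rng):
        X = rng.normal(size=(15, 3))
        ds = [kmeans_cluster(X, k).d for k in range(1, 8)]
        assert all(a >= b - 1e-9 for a, b in zip(ds, ds[1:]))

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans_cluster(rng.normal(size=(3, 2)), 4)


class TestElbow:
    def test_single_kink_detected(self):
        ks = np.arange(1, 9)
        d = np.where(ks <= 4, 100 - 20 * (ks - 1), 40 - 2 * (ks - 4))
        k, has = elbow_select(ks, d)
        assert has and k == 4

    def test_straight_line_has_no_elbow(self):
        ks = np.arange(1, 7)
        k, has = elbow_select(ks, 60 - 10.0 * ks)
        assert not has

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            elbow_select([1, 2], [3.0, 1.0])


class TestPsychophysicalKernel:
    def _recs(self, frames1, frames2):
        recs = []
        for frames, dec in ((frames1, 1), (frames2, 2)):
            for f in frames:
                recs.append(make_record(len(f), True, decision=dec, obs=f,
                                        n_obs=f.shape[1]))
        return recs

    def test_identical_decision_sets_give_zero_kernel(self, rng):
        f = rng.uniform(size=(5, 4))
        pk = psychophysical_kernel(self._recs([f], [f.copy()]),
                                   pre_stimulus_steps=3)
        assert np.allclose(np.vstack(pk.amplitude), 0.0)

    def test_hand_built_two_trial_difference(self):
        f1 = np.zeros((5, 4))
        f1[3:] = 0.8
        f2 = np.zeros((5, 4))
        f2[3:] = 0.2
        pk = psychophysical_kernel(self._recs([f1], [f2]), pre_stimulus_steps=3)
        assert len(pk) == 2
        assert np.allclose(pk.amplitude, 0.6)
        assert np.allclose(pk.image.iloc[0], 0.6)

    def test_pooled_kernel_is_weighted_recombination(self, rng):
        # linearity of the per-step means across sub-datasets
        fA = [rng.uniform(size=(5, 4)) for _ in range(2)]
        fB = [rng.uniform(size=(5, 4)) for _ in range(3)]
        f2 = [rng.uniform(size=(5, 4)) for _ in range(2)]
        pooled = psychophysical_kernel(self._recs(fA + fB, f2), pre_stimulus_steps=3)
        m1 = (2 * np.mean([f[4] for f in fA], axis=0)
              + 3 * np.mean([f[4] for f in fB], axis=0)) / 5
        expect = m1 - np.mean([f[4] for f in f2], axis=0)
        assert np.allclose(pooled[pooled.t == 4].image.iloc[0], expect)

    def test_single_decision_dataset_rejected(self, rng):
        f = rng.uniform(size=(5, 4))
        with pytest.raises(ValueError):
            psychophysical_kernel(self._recs([f], []), pre_stimulus_steps=3)


def test_feature_matrix_shapes_and_zscoring(rng):
    recs = [make_record(4, True, noise=n, label=l,
                        hidden=rng.uniform(size=(4, 3)))
            for n in (0.0, 0.5) for l in (0, 1) for _ in range(2)]
    courses = unit_time_courses(recs)
    X = unit_feature_matrix(courses)
    assert X.shape == (3, 4 * 4)
    assert np.allclose(X.mean(axis=1), 0.0, atol=1e-12)
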