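import numpy as np
import pytest

from svdecode.decoding import (HIGH, LOW, BetaSeries, cross_context_decode,
                               label_by_median_split, loro_cv_decode,
                               remove_outlier_trials)


def _series(matrix, run_ids, trial_ids=None, roi_id=0):
    matrix = np.asarray(matrix, dtype=float)
    if trial_ids is None:
        trial_ids = np.arange(matrix.shape[0])
    return BetaSeries(roi_id=roi_id, matrix=matrix,
                      run_ids=np.asarray(run_ids), trial_ids=trial_ids)


class TestMedianSplit:
    def test_ties_balance_the_classes(self):
        sv = np.array([0.2, 0.4, 0.6, 0.6, 0.8, 1.0])
        runs = np.ones(6, dtype=int)
        ctx = np.array(["risk"] * 6)
        lab = label_by_median_split(sv, runs, ctx, seed=0)
        assert (lab.labels == LOW).sum() == 3
        assert (lab.labels == HIGH).sum() == 3
        assert lab.labels[0] == LOW and lab.labels[1] == LOW
        assert lab.labels[4] == HIGH and lab.labels[5] == HIGH
        # the two median-tied trials split one to each class
        assert sorted(lab.labels[2:4]) == [LOW, HIGH]

    def test_distinct_even_values_split_exactly_in_half(self):
        sv = np.linspace(0.1, 1.0, 20)
        lab = label_by_median_split(sv, np.ones(20, dtype=int),
                                    np.array(["risk"] * 20), seed=0)
        assert (lab.labels == LOW).sum() == 10
        assert np.array_equal(lab.labels, (sv > np.median(sv)).astype(int))

    def test_within_context_split_balances_each_context(self):
        # disjoint SV ranges per context: an overall split would confound
        # label with context; per-context medians balance each
        sv = np.concatenate([np.linspace(0.1, 0.3, 10),
                             np.linspace(0.7, 1.0, 10)])
        ctx = np.array(["risk"] * 10 + ["ambiguity"] * 10)
        runs = np.ones(20, dtype=int)
        lab = label_by_median_split(sv, runs, ctx,
                                    split_kind="within_context", seed=0)
        for c in ("risk", "ambiguity"):
            sel = ctx == c
            assert (lab.labels[sel] == LOW).sum() == 5

    def test_degenerate_constant_svs_rejected(self):
        with pytest.raises(ValueError):
            label_by_median_split(np.ones(6), np.ones(6, dtype=int),
                                  np.array(["risk"] * 6), seed=0)

    def test_seed_determinism_of_tie_assignment(self):
        sv = np.array([0.5] * 6 + [0.1, 1.0])
        runs = np.ones(8, dtype=int)
        ctx = np.array(["risk"] * 8)
        a = label_by_median_split(sv, runs, ctx, seed=3)
        b = label_by_median_split(sv, runs, ctx, seed=3)
        assert np.array_equal(a.labels, b.labels)


class TestOutlierRemoval:
    def test_constructed_outlier_is_dropped(self):
        rng = np.random.default_rng(0)
        mat = rng.normal(size=(60, 10))
        mat[17] += 10.0  # +10 SD shift of the spatial mean
        out = remove_outlier_trials(_series(mat, np.repeat([1, 2, 3], 20)))
        assert 17 in out.dropped_trial_ids
        assert out.n_trials == 59

    def test_homogeneous_noise_drops_few_trials(self):
        rng = np.random.default_rng(1)
        dropped = 0
        total = 0
        for i in range(30):
            mat = rng.normal(size=(120, 12))
            out = remove_outlier_trials(_series(mat, np.repeat([1, 2, 3, 4], 30)))
            dropped += 120 - out.n_trials
            total += 120
        # Gaussian 3-SD tail: ~0.27% expected; allow generous sampling slack
        assert dropped / total < 0.02
        assert dropped / total >= 0.0

    def test_requires_minimum_trials(self):
        with pytest.raises(ValueError):
            remove_outlier_trials(_series(np.zeros((5, 3)), np.ones(5, dtype=int)))


def _labeled(labels, contexts=None, trial_ids=None):
    from svdecode.decoding import LabeledTrials
    labels = np.asarray(labels)
    n = len(labels)
    if contexts is None:
        contexts = np.array(["risk"] * n)
    if trial_ids is None:
        trial_ids = np.arange(n)
    return LabeledTrials(trial_ids=trial_ids, labels=labels,
                         contexts=np.asarray(contexts), split_kind="overall")


def _separable_problem(n_per_run=24, n_runs=4, n_vox=10, gap=3.0, noise=0.3,
                       seed=0):
    rng = np.random.default_rng(seed)
    n = n_per_run * n_runs
    labels = np.tile(np.repeat([LOW, HIGH], n_per_run // 2), n_runs)
    direction = rng.normal(size=n_vox)
    direction /= np.linalg.norm(direction)
    mat = (np.where(labels == HIGH, gap, -gap)[:, None] * direction
           + noise * rng.normal(size=(n, n_vox)))
    runs = np.repeat(np.arange(1, n_runs + 1), n_per_run)
    return _series(mat, runs), _labeled(labels)


class TestLoroCv:
    def test_four_runs_give_four_folds(self):
        series, labels = _separable_problem()
        res = loro_cv_decode(series, labels, n_boot=2, seed=0)
        assert len(res.fold_accuracies) == 4

    def test_separable_patterns_decode_near_perfectly(self):
        series, labels = _separable_problem()
        res = loro_cv_decode(series, labels, n_boot=5, seed=0)
        assert res.mean_accuracy >= 0.95

    def test_shuffled_labels_decode_at_chance(self):
        rng = np.random.default_rng(2)
        accs = []
        for i in range(10):
            series, labels = _separable_problem(seed=i)
            shuffled = _labeled(rng.permutation(labels.labels))
            accs.append(loro_cv_decode(series, shuffled, n_boot=2,
                                       seed=i).mean_accuracy)
        assert np.mean(accs) == pytest.approx(0.5, abs=0.06)

    def test_balanced_labels_with_single_boot_are_deterministic(self):
        series, labels = _separable_problem(noise=1.5)
        a = loro_cv_decode(series, labels, n_boot=1, seed=0)
        b = loro_cv_decode(series, labels, n_boot=1, seed=99)
        # balanced classes: no subsampling happens, so the seed is inert
        np.testing.assert_array_equal(a.fold_accuracies, b.fold_accuracies)

    def test_accuracy_invariant_to_voxel_permutation_and_rescaling(self):
        series, labels = _separable_problem(seed=5)
        base = loro_cv_decode(series, labels, n_boot=1, seed=0)
        rng = np.random.default_rng(0)
        perm = rng.permutation(series.n_voxels)
        permuted = _series(series.matrix[:, perm], series.run_ids)
        res_p = loro_cv_decode(permuted, labels, n_boot=1, seed=0)
        np.testing.assert_array_equal(base.fold_accuracies, res_p.fold_accuracies)
        scaled = _series(series.matrix * 2.0, series.run_ids)
        res_s = loro_cv_decode(scaled, labels, n_boot=1, seed=0)
        np.testing.assert_array_equal(base.fold_accuracies, res_s.fold_accuracies)

    def test_accuracy_monotone_in_signal_amplitude(self, schedule, params,
                                                   small_atlas, sv_labels):
        from svdecode.synth import SignalSpec, simulate_beta_series
        rid = small_atlas.roi_ids[0]
        accs = []
        for amp in (0.0, 1.5, 5.0):
            sig = SignalSpec(atlas=small_atlas, amplitude_per_roi=amp,
                             noise_sd=1.0, voxel_weight_seed=4)
            beta = simulate_beta_series(schedule, params, sig, seed=6)
            accs.append(loro_cv_decode(beta[rid], sv_labels, n_boot=3,
                                       seed=0).mean_accuracy)
        assert accs[0] < accs[2]
        assert accs[1] <= accs[2] + 0.05

    def test_single_label_training_fold_is_skipped(self):
        series, labels = _separable_problem(n_per_run=8, n_runs=2)
        one_label = _labeled(np.zeros(16, dtype=int))
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                loro_cv_decode(series, one_label, n_boot=1, seed=0)


class TestCrossContext:
    def _two_context_problem(self, mix, seed=0, amp=4.0):
        from svdecode.atlas import make_atlas
        from svdecode.synth import SignalSpec, simulate_beta_series
        from svdecode import build_choice_set, subjective_value
        from svdecode.decoding import label_by_median_split
        sched = build_choice_set(4, seed=seed)
        atl = make_atlas({"default": 1}, (16, 20), seed=1)
        params_a, params_b = 0.7, 0.3
        from svdecode.choice import PreferenceParams
        p = PreferenceParams(params_a, params_b, -2.0)
        sig = SignalSpec(atlas=atl, amplitude_per_roi=amp, noise_sd=1.0,
                         shared_across_contexts=mix, voxel_weight_seed=seed)
        beta = simulate_beta_series(sched, p, sig, seed=seed + 50)
        sv = np.atleast_1d(subjective_value(
            sched.win_probs, sched.ambiguities, sched.lottery_values,
            p.alpha, p.beta))
        labels = label_by_median_split(sv, sched.run_ids, sched.contexts,
                                       split_kind="within_context", seed=0)
        return beta[0], labels

    def test_shared_patterns_generalize_across_contexts(self):
        series, labels = self._two_context_problem(mix=1.0)
        res = cross_context_decode(series, labels, n_boot=3, seed=0)
        assert res.mean_accuracy > 0.7

    def test_context_specific_patterns_do_not_generalize(self):
        accs_cross, accs_within = [], []
        for i in range(4):
            series, labels = self._two_context_problem(mix=0.0, seed=i)
            accs_cross.append(cross_context_decode(
                series, labels, n_boot=3, seed=0).mean_accuracy)
            accs_within.append(loro_cv_decode(
                series, labels, n_boot=3, seed=0).mean_accuracy)
        assert np.mean(accs_within) > 0.7
        assert np.mean(accs_cross) == pytest.approx(0.5, abs=0.07)

    def test_direction_symmetry_for_exchangeable_generator(self):
        series, labels = self._two_context_problem(mix=1.0)
        res = cross_context_decode(series, labels, n_boot=3, seed=0)
        # folds 0-3 are risk->ambiguity, 4-7 ambiguity->risk
        d = abs(res.fold_accuracies[:4].mean() - res.fold_accuracies[4:].mean())
        assert d < 0.15
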