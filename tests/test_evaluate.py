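import numpy as np
import pandas as pd
import pytest

from livesort.evaluate import (
    CHANCE_12WAY,
    DroppingCurve,
    asymptote_model,
    bin_counts,
    compare_methods,
    decode_timecourse,
    dropping_curve,
    fit_asymptote,
    fit_tuning,
    match_trains,
    match_units,
    psth_compare,
)

FS = 30000.0


class TestMatching:
    def test_identical_trains_score_one(self):
        t = np.arange(100, 10000, 300)
        fp, fm, score = match_trains(t, t, 15)
        assert (fp, fm, score) == (0.0, 0.0, 1.0)

    def test_half_deleted_reference_scores_half(self):
        b = np.arange(100, 30100, 300)  # reference
        a = b[::2]  # test train missing half
        fp, fm, score = match_trains(a, b, 15)
        assert fp == 0.0
        assert fm == pytest.approx(0.5)
        assert score == pytest.approx(0.5)

    def test_nine_of_ten_sits_exactly_at_cutoff(self):
        b = np.arange(10) * 1000
        a = np.concatenate([b[:9], [50_000]])
        fp, fm, score = match_trains(np.sort(a), b, 15)
        assert score == pytest.approx(0.8)
        res = match_units({0: np.sort(a)}, {0: b}, tol_samples=15)
        assert len(res.matched) == 1  # >= 0.8 counts as matched

    def test_empty_train_forces_unit_rates(self):
        b = np.arange(5) * 1000
        fp, fm, score = match_trains(np.empty(0, dtype=int), b, 15)
        assert fm == 1.0 and score == 0.0

    def test_pairing_is_one_to_one_by_score(self):
        base = np.arange(100, 50000, 400)
        trains_a = {0: base, 1: base + 3}
        trains_b = {10: base}
        res = match_units(trains_a, trains_b, tol_samples=15)
        # exactly one pair may claim unit 10, and it is the exact match
        claimed = res.pairs[res.pairs["unit_b"] == 10]
        assert len(claimed) == 1
        assert claimed.iloc[0]["unit_a"] == 0


class TestPSTH:
    def _onsets(self, n=50):
        return (np.arange(n) * 2.0 + 1.0) * FS

    def test_identical_trains_correlate_perfectly(self):
        rng = np.random.default_rng(0)
        onsets = self._onsets()
        train = np.sort(rng.integers(0, int(onsets[-1] + FS), 4000))
        _, _, r = psth_compare(train, train, onsets, FS)
        assert r == pytest.approx(1.0)

    def test_independent_poisson_trains_decorrelated(self):
        rng = np.random.default_rng(1)
        onsets = self._onsets(100)
        hi = int(onsets[-1] + 2 * FS)
        a = np.sort(rng.integers(0, hi, 8000))
        b = np.sort(rng.integers(0, hi, 8000))
        _, _, r = psth_compare(a, b, onsets, FS)
        assert abs(r) < 0.3

    def test_constant_psths_give_missing_value(self):
        onsets = self._onsets(5)
        _, _, r = psth_compare(
            np.empty(0, dtype=int), np.empty(0, dtype=int), onsets, FS
        )
        assert np.isnan(r)


class TestTuning:
    def _trials(self, reps=20):
        rows = []
        t = FS
        for _ in range(reps):
            for d in np.arange(0, 360, 30):
                rows.append((int(t), float(d), "stim"))
                t += 0.4 * FS
        return pd.DataFrame(rows, columns=["onset_sample", "direction_deg", "condition"])

    def test_flat_response_is_not_well_fit(self):
        trials = self._trials()
        train = np.concatenate(
            [np.arange(o + 1500, o + 7500, 700) for o in trials["onset_sample"]]
        )
        _, fit = fit_tuning(np.sort(train), trials, FS)
        assert not fit.well_fit

    def test_missing_directions_rejected(self):
        trials = self._trials().iloc[:6]
        with pytest.raises(ValueError, match="12 directions"):
            fit_tuning(np.array([100]), trials, FS)

    def test_model_generated_tuning_recovered(self):
        from livesort.benchmarks import von_mises_recovery_benchmark

        res = von_mises_recovery_benchmark(seed=0)
        assert res["mu_error_deg"] < 1.0
        assert res["r_squared"] > 0.99
        assert not res["flat_well_fit"]


class TestDecoding:
    def _separable_counts(self, n_bins=3, trials_per_class=6):
        dirs = np.repeat(np.arange(0, 360, 30), trials_per_class)
        counts = np.zeros((len(dirs), 12, n_bins))
        for i, d in enumerate(dirs):
            counts[i, int(d // 30), :] = 5.0
        return counts, dirs

    def test_perfectly_separable_counts_decode_to_one(self):
        counts, dirs = self._separable_counts()
        acc, sem = decode_timecourse(counts, dirs, seed=42)
        assert np.allclose(acc, 1.0)

    def test_class_below_fold_count_rejected(self):
        counts, dirs = self._separable_counts(trials_per_class=3)
        with pytest.raises(ValueError, match="trials"):
            decode_timecourse(counts, dirs, seed=42)

    def test_trial_order_does_not_matter_in_expectation(self):
        # resampling oracle: permuting trial order only relabels CV folds,
        # so seed-averaged accuracy is unchanged
        rng = np.random.default_rng(2)
        counts, dirs = self._separable_counts(n_bins=1, trials_per_class=8)
        counts = counts + rng.normal(0, 2.0, counts.shape)
        perm = rng.permutation(len(dirs))
        accs = [decode_timecourse(counts, dirs, seed=s)[0][0] for s in range(6)]
        accs_p = [
            decode_timecourse(counts[perm], dirs[perm], seed=s)[0][0] for s in range(6)
        ]
        assert abs(np.mean(accs) - np.mean(accs_p)) < 0.08


class TestDroppingCurve:
    def _counts(self, informative, n_units=12, per_class=20, seed=0):
        rng = np.random.default_rng(seed)
        dirs = np.repeat(np.arange(0, 360, 30), per_class)
        counts = rng.poisson(3.0, (len(dirs), n_units)).astype(float)
        if informative:
            for i, d in enumerate(dirs):
                counts[i, int(d // 30) % n_units] += 8.0
        return counts, dirs

    def test_uninformative_units_sit_at_chance(self):
        counts, dirs = self._counts(False)
        curve = dropping_curve(counts, dirs, seed=0, n_folds=10)
        assert abs(curve.mean_accuracy[0] - CHANCE_12WAY) < 0.06

    def test_informative_curve_exceeds_chance_and_is_ordered(self):
        counts, dirs = self._counts(True)
        curve = dropping_curve(counts, dirs, seed=0, n_folds=10)
        assert curve.mean_accuracy[-1] > 3 * CHANCE_12WAY
        assert np.all(np.diff(curve.unit_counts) > 0)

    def test_exhaustive_draw_at_full_unit_count(self):
        counts, dirs = self._counts(True, n_units=10)
        curve = dropping_curve(counts, dirs, seed=0, n_folds=10)
        assert curve.unit_counts[-1] == 10

    def test_too_few_units_rejected(self):
        counts, dirs = self._counts(True, n_units=4)
        with pytest.raises(ValueError, match="10 units"):
            dropping_curve(counts, dirs, seed=0)


class TestAsymptote:
    def test_model_identities(self):
        # y(0) = c for any parameters; y(k) -> A as k -> infinity
        for A, w, t1, t2 in [(0.7, 0.3, 5.0, 100.0), (0.9, 1.0, 2.0, 50.0)]:
            assert asymptote_model(0.0, A, w, t1, t2) == pytest.approx(CHANCE_12WAY)
            assert asymptote_model(1e9, A, w, t1, t2) == pytest.approx(A)

    def test_noiseless_curve_recovered_to_a_thousandth(self):
        from livesort.benchmarks import asymptote_recovery_benchmark

        res = asymptote_recovery_benchmark()
        assert res["abs_error"] < 0.001

    def test_failure_falls_back_to_last_three_points(self):
        k = np.arange(10, 70, 10)
        y = np.array([0.2, np.nan, 0.25, 0.4, 0.45, 0.5])  # NaN breaks the fit
        fit = fit_asymptote(DroppingCurve(unit_counts=k, mean_accuracy=y,
                                          sem=np.zeros(6)))
        assert fit.fallback_used and not fit.converged
        assert fit.A == pytest.approx(np.mean(y[-3:]))

    def test_noisy_curves_recover_asymptote(self):
        # median |A_hat - A| <= 0.01 over SEM-scale noisy curves
        rng = np.random.default_rng(3)
        k = np.arange(10, 401, 10)
        errors = []
        for _ in range(100):
            sem = np.full(len(k), 0.01)
            y = asymptote_model(k, 0.72, 0.5, 10.0, 200.0) + rng.normal(0, 0.01, len(k))
            y = np.clip(y, 0.0, 1.0)
            fit = fit_asymptote(DroppingCurve(unit_counts=k, mean_accuracy=y, sem=sem))
            errors.append(abs(fit.A - 0.72))
        assert np.median(errors) <= 0.01


class TestCompareMethods:
    def test_equal_lists_give_zero_difference(self):
        a = [0.7, 0.72, 0.68, 0.71, 0.69]
        res = compare_methods(a, a)
        assert res["mean_difference"] == 0.0
        assert res["p_value"] == 1.0 and res["all_zero"]

    def test_constant_shift_reaches_minimal_p(self):
        a = np.array([0.70, 0.72, 0.68, 0.71, 0.69, 0.73])
        res = compare_methods(a, a + 0.05)
        # exact signed-rank enumeration: all-same-sign is the extreme table,
        # two-sided p = 2 / 2^n
        assert res["p_value"] == pytest.approx(2 / 2**6)

    def test_sign_flip_antisymmetry(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0.5, 0.9, 8)
        b = a + rng.normal(0, 0.05, 8)
        assert compare_methods(a, b)["mean_difference"] == pytest.approx(
            -compare_methods(b, a)["mean_difference"]
        )


def test_bin_counts_shapes_and_values():
    trains = {0: np.array([30000 + 1500, 30000 + 4500]), 1: np.array([0])}
    counts, centers = bin_counts(trains, np.array([30000]), FS)
    assert counts.shape == (1, 2, len(centers))
    # half-open 100 ms windows: the 50 ms spike lands in centers 10..100,
    # the 150 ms spike in centers 110..200 -> 10 bins each
    idx = np.argmin(np.abs(centers - 100.0))
    assert counts[0, 0, idx] == 1
    assert counts[0, 0].sum() == 20
    assert counts[0, 1].sum() == 0
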