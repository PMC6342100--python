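import warnings

import numpy as np
import pytest

from ethotree.calibration import (
    optimize_threshold,
    select_training_segments,
    segment_feature_matrix,
    stationary_quantile_threshold,
    histogram_compare,
    rf_window_benchmark,
    windowed_ddba_values,
)
from ethotree.io import ObservationLog
from ethotree.preprocess import DynamicTrace
from ethotree.simulate import generate_still_trace, scenario_library


def _dyn_from_x(dx):
    n = len(dx)
    z = np.zeros(n)
    return DynamicTrace(
        t=np.arange(n), static_x=z, static_y=z, static_z=z + 1,
        dyn_x=np.asarray(dx, float), dyn_y=z.copy(), dyn_z=z.copy(),
        temp_smooth=z + 20,
    )


class TestStationaryQuantile:
    def test_all_zero_windows_give_zero_threshold(self):
        dyn = _dyn_from_x(np.zeros(14 * 1200))
        assert stationary_quantile_threshold([dyn]) == 0.0

    def test_matches_sorted_array_interpolation_oracle(self, rng):
        dyn = _dyn_from_x(rng.normal(0, 0.1, 14 * 2000))
        vals = windowed_ddba_values(dyn, 14)
        got = stationary_quantile_threshold([dyn], q=0.999)
        # independent order-statistic interpolation
        s = np.sort(vals)
        h = (len(s) - 1) * 0.999
        lo, hi = int(np.floor(h)), int(np.ceil(h))
        expected = s[lo] + (h - lo) * (s[hi] - s[lo])
        assert got == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_q(self, rng):
        dyn = _dyn_from_x(rng.normal(0, 0.1, 14 * 2000))
        qs = [0.5, 0.9, 0.99, 0.999]
        thrs = [stationary_quantile_threshold([dyn], q=q) for q in qs]
        assert thrs == sorted(thrs)

    def test_warns_on_small_sample_and_errors_on_empty(self):
        dyn = _dyn_from_x(np.zeros(14 * 10))
        with pytest.warns(UserWarning, match="windows"):
            stationary_quantile_threshold([dyn])
        with pytest.raises(ValueError):
            stationary_quantile_threshold([])

    def test_still_noise_threshold_within_analytic_envelope(self):
        # mean window delta-DBA for N(0, sd^2) noise is
        # 3*(t-1)*sd*sqrt(2)*sqrt(2/pi); the 99.9% quantile must sit above
        # the mean but within a few sds of the analytic sum
        cfg = scenario_library()["field_like"]
        sd = cfg.noise_sd["not_moving"][0]
        still = generate_still_trace(cfg, 14 * 3000, seed=5)
        thr = stationary_quantile_threshold([still])
        mean = 3 * 13 * sd * 2 / np.sqrt(np.pi)
        assert mean < thr < mean * 2
        # same order of magnitude as the field-calibrated gate value
        assert 0.3 < thr < 3.5


class TestPurityRules:
    def _obs(self, intervals):
        return ObservationLog("d", intervals)

    def _dyn(self, n):
        return _dyn_from_x(np.zeros(n))

    def test_fully_feeding_window_kept(self):
        segs = select_training_segments(
            self._obs([(0, 10, "feeding")]), self._dyn(10), 10
        )
        assert [(s.label, s.purity) for s in segs] == [("feeding", 1.0)]

    def test_foraging_with_any_running_rejected(self):
        segs = select_training_segments(
            self._obs([(0, 8, "foraging"), (8, 10, "running")]),
            self._dyn(10), 10,
        )
        assert segs == []

    def test_majority_running_kept_at_51_percent(self):
        segs = select_training_segments(
            self._obs([(0, 3, "running"), (3, 4, "foraging")]),
            self._dyn(4), 4,
        )
        assert [s.label for s in segs] == ["running"]

    def test_half_running_rejected(self):
        segs = select_training_segments(
            self._obs([(0, 2, "running"), (2, 4, "foraging")]),
            self._dyn(4), 4,
        )
        assert segs == []

    def test_75_percent_foraging_without_running_kept(self):
        segs = select_training_segments(
            self._obs([(0, 3, "foraging"), (3, 4, "not_moving")]),
            self._dyn(4), 4,
        )
        assert [s.label for s in segs] == ["foraging"]
        # 74% foraging is not enough
        segs = select_training_segments(
            self._obs([(0, 7, "foraging"), (7, 10, "not_moving")]),
            self._dyn(10), 10,
        )
        assert segs == []

    def test_99_percent_feeding_rejected(self):
        segs = select_training_segments(
            self._obs([(0, 9, "feeding"), (9, 10, "foraging")]),
            self._dyn(10), 10,
        )
        assert [s.label for s in segs] == []

    def test_selection_invariant_to_interval_order(self):
        ivs = [(0, 3, "running"), (3, 4, "foraging"), (4, 8, "feeding"),
               (8, 12, "running")]
        a = select_training_segments(self._obs(ivs), self._dyn(12), 4)
        b = select_training_segments(
            self._obs(list(reversed(ivs))), self._dyn(12), 4
        )
        assert [(s.start, s.end, s.label) for s in a] == [
            (s.start, s.end, s.label) for s in b
        ]


class TestOptimizeThreshold:
    def test_perfect_separation(self, rng):
        va = rng.uniform(0, 0.9, 100)
        vb = rng.uniform(1.1, 2.0, 100)
        values = np.concatenate([va, vb])
        labels = np.array(["a"] * 100 + ["b"] * 100)
        res = optimize_threshold(values, labels)
        assert res.overall == pytest.approx(1.0)
        # ties resolve to the lowest perfect candidate: the left edge of
        # the gap between the classes
        assert va.max() - 0.011 <= res.threshold <= vb.min()
        assert res.high_label == "b"

    def test_matches_fine_grid_oracle_on_overlapping_gaussians(self, rng):
        va = rng.normal(0, 1, 400)
        vb = rng.normal(2, 1, 400)
        values = np.concatenate([va, vb])
        labels = np.array(["a"] * 400 + ["b"] * 400)
        res = optimize_threshold(values, labels, grid_step=0.01)
        fine = optimize_threshold(values, labels, grid_step=0.001)
        assert abs(res.threshold - fine.threshold) <= 0.02 + 1e-12
        assert res.overall <= fine.overall + 1e-12

    def test_no_signal_gives_half_accuracy(self, rng):
        values = rng.normal(0, 1, 2000)
        labels = np.array(["a", "b"] * 1000)
        res = optimize_threshold(values, labels)
        assert abs(res.overall - 0.5) < 0.07

    def test_tie_breaks_to_lowest_threshold(self):
        values = np.array([0.0, 0.0, 1.0, 1.0])
        labels = np.array(["a", "a", "b", "b"])
        res = optimize_threshold(values, labels, grid_step=0.25)
        # all candidates in (0, 1) are perfect; the smallest wins
        assert res.overall == 1.0
        assert res.threshold == pytest.approx(0.0)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            optimize_threshold(np.ones(5), np.array(["a"] * 5))

    def test_recovers_generator_boundary_over_seeds(self):
        # two classes split at theta with symmetric noise: the scan argmax
        # lands within 2 grid steps + a noise-scaled slack, in >= 18/20 seeds
        theta, step = 1.3, 0.01
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            a = theta - np.abs(r.normal(0.3, 0.1, 300))
            b = theta + np.abs(r.normal(0.3, 0.1, 300))
            res = optimize_threshold(
                np.concatenate([a, b]),
                np.array(["lo"] * 300 + ["hi"] * 300),
                grid_step=step,
            )
            if abs(res.threshold - theta) <= 2 * step + 0.05:
                hits += 1
        assert hits >= 18


class TestHistogramCompare:
    def test_separable_statistic_ranks_first(self, rng):
        import pandas as pd
        from ethotree.features import FEATURE_NAMES

        n = 200
        df = pd.DataFrame(
            {name: rng.normal(0, 1, n) for name in FEATURE_NAMES}
        )
        labels = np.array(["a"] * 100 + ["b"] * 100)
        df["odba"] = np.where(labels == "a", 0.0, 10.0) + rng.normal(0, 0.1, n)
        df["label"] = labels
        ranking = histogram_compare(df)
        assert ranking.iloc[0]["statistic"] == "odba"
        assert ranking.iloc[0]["separability"] == pytest.approx(1.0)
        # everything else carries no signal
        assert ranking.iloc[5]["separability"] < 0.75


class TestRFBenchmark:
    def test_separable_emissions_score_high_and_permuted_labels_chance(
        self, separable_run, rng
    ):
        from ethotree.simulate import truth_to_observation_log

        dense = truth_to_observation_log(separable_run.truth)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tab = rf_window_benchmark(
                dense, separable_run.dyn, windows=(10,), n_trees=100, seed=5
            )
        assert tab.iloc[0]["acc_overall"] >= 0.95
        # permutation null: shuffled labels on a class-balanced pool leave
        # ~1/3 accuracy for 3 classes
        segs = select_training_segments(dense, separable_run.dyn, 10)
        by_class = {}
        for s in segs:
            by_class.setdefault(s.label, []).append(s)
        balanced = sum((v[:150] for v in by_class.values()), [])
        fm = segment_feature_matrix(separable_run.dyn, balanced)
        from sklearn.ensemble import RandomForestClassifier
        from sklearn.model_selection import train_test_split
        from ethotree.features import FEATURE_NAMES

        y = rng.permutation(fm["label"].to_numpy())
        Xtr, Xte, ytr, yte = train_test_split(
            fm[list(FEATURE_NAMES)], y, train_size=0.75, random_state=0
        )
        acc = RandomForestClassifier(
            n_estimators=100, random_state=0
        ).fit(Xtr, ytr).score(Xte, yte)
        assert abs(acc - 1 / 3) < 0.15

    def test_same_seed_reproduces_table(self, field_run):
        from ethotree.simulate import truth_to_observation_log

        dense = truth_to_observation_log(field_run.truth)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = rf_window_benchmark(
                dense, field_run.dyn, windows=(14,), n_trees=50, seed=9
            )
            b = rf_window_benchmark(
                dense, field_run.dyn, windows=(14,), n_trees=50, seed=9
            )
        assert a.equals(b)
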