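"""Trial summaries, feature extraction, selection, classification, tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import touchcontact as tc
from touchcontact.features import (
    benjamini_hochberg,
    build_feature_table,
    chance_level,
    classify_trials,
    compare_gestures,
    extract_feature_set,
    feature_pvalues,
    permutation_importance,
    select_relevant_features,
    summarize_trial,
)
from touchcontact.kinematics import ContactAttributeSeries


def make_series(n=40, f=30.0, **channels):
    """Rectangular series with given channel overrides (defaults zeros)."""
    base = dict(
        timestamps=np.arange(n) / f,
        contact_flags=np.ones(n, bool),
        v_abs=np.zeros(n), v_vt=np.zeros(n), v_lg=np.zeros(n), v_lt=np.zeros(n),
        area=np.zeros(n), depth=np.zeros(n), sampling_rate=f,
    )
    base.update(channels)
    return ContactAttributeSeries(**base)


class TestSummarizeTrial:
    def test_signed_velocities_enter_as_absolute_values(self):
        s = make_series(n=2, v_lg=np.array([-10.0, 10.0]))
        s.velocity_valid = np.ones(2, bool)
        assert summarize_trial(s)["Vlg"] == pytest.approx(10.0)

    def test_constant_area_mean(self):
        s = make_series(area=np.full(40, 30.0))
        assert summarize_trial(s)["area"] == pytest.approx(30.0)

    def test_duration_passes_through(self):
        s = make_series(n=45)
        assert summarize_trial(s)["duration"] == pytest.approx(1.5)

    def test_zero_contact_gives_zero_summary_with_warning(self):
        s = make_series(contact_flags=np.zeros(40, bool))
        with pytest.warns(RuntimeWarning, match="no contact"):
            out = summarize_trial(s)
        assert all(v == 0.0 for v in out.values())


class TestExtractFeatureSet:
    def test_constant_signal_statistics(self):
        c = 3.0
        s = make_series(area=np.full(40, c))
        feats = extract_feature_set(s)
        assert feats["area__std"] == 0.0
        assert feats["area__energy"] == pytest.approx(40 * c**2)
        assert feats["area__trend"] == pytest.approx(0.0, abs=1e-12)

    def test_sinusoid_peaks_at_expected_fourier_bin(self):
        # 3 Hz sampled at 30 Hz over N=40 frames -> bin 3*N/30 = 4
        n, f, freq = 40, 30.0, 3.0
        t = np.arange(n) / f
        s = make_series(n=n, v_abs=np.sin(2 * np.pi * freq * t))
        feats = extract_feature_set(s)
        amps = {k: feats[f"Vabs__fourier{k}"] for k in range(1, 6)}
        assert max(amps, key=amps.get) == 4
        # oracle: discrete transform amplitude computed directly
        expected = np.abs(np.fft.rfft(np.sin(2 * np.pi * freq * t)))[4]
        assert amps[4] == pytest.approx(expected)

    def test_deterministic_feature_order(self):
        s = make_series(depth=np.linspace(0, 2, 40))
        a = extract_feature_set(s)
        b = extract_feature_set(s)
        assert list(a.index) == list(b.index)
        assert (a == b).all()

    def test_too_short_series_error_names_minimum(self):
        with pytest.raises(ValueError, match="8"):
            extract_feature_set(make_series(n=5))

    def test_no_missing_values(self):
        s = make_series()  # all-zero channels: many degenerate statistics
        feats = extract_feature_set(s)
        assert np.isfinite(feats.to_numpy()).all()


def bh_oracle(pvals, q):
    """Textbook step-up: largest k with p_(k) <= k*q/m, keep those ranks."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    k_star = 0
    for rank, i in enumerate(order, start=1):
        if pvals[i] <= rank * q / m:
            k_star = rank
    keep = [False] * m
    for rank, i in enumerate(order, start=1):
        if rank <= k_star:
            keep[i] = True
    return keep


class TestBenjaminiHochberg:
    def test_toy_example(self):
        keep = benjamini_hochberg([0.001, 0.01, 0.02, 0.9], q=0.05)
        assert keep.tolist() == [True, True, True, False]

    def test_all_ones_none_kept(self):
        assert not benjamini_hochberg([1.0] * 6, q=0.05).any()

    def test_matches_oracle_on_all_short_lists(self):
        grid = [0.001, 0.011, 0.02, 0.049, 0.2, 0.6, 1.0]
        rng = np.random.default_rng(0)
        for m in range(1, 9):
            for _ in range(30):
                p = list(rng.choice(grid, size=m))
                assert benjamini_hochberg(p, 0.05).tolist() == bh_oracle(p, 0.05)

    def test_noise_feature_rejected_in_simulations(self):
        rng = np.random.default_rng(1)
        rejected = 0
        n = 40
        labels = np.repeat(["a", "b"], n // 2)
        for _ in range(100):
            informative = np.where(labels == "a", 0.0, 3.0) + rng.normal(0, 1, n)
            noise = rng.normal(0, 1, n)
            table = tc.FeatureTable(
                matrix=pd.DataFrame({"signal__x": informative, "noise__x": noise})
            )
            kept = select_relevant_features(table, labels, q=0.05)
            if "noise__x" not in kept.feature_names:
                rejected += 1
        assert rejected >= 95

    def test_constant_feature_gets_p_one(self):
        labels = np.repeat(["a", "b"], 10)
        table = tc.FeatureTable(
            matrix=pd.DataFrame({"const__x": np.ones(20),
                                 "vary__x": np.arange(20.0)})
        )
        assert feature_pvalues(table, labels)["const__x"] == 1.0


class TestClassifyTrials:
    def test_perfectly_separated_classes(self):
        rng = np.random.default_rng(2)
        n = 40
        labels = np.repeat(["a", "b"], n // 2)
        x = np.where(labels == "a", 0.0, 10.0) + rng.normal(0, 0.1, n)
        table = tc.FeatureTable(matrix=pd.DataFrame({"x": x}))
        res = classify_trials(table, labels, seed=0, n_estimators=50)
        assert res.accuracy == 100.0

    def test_split_sizes_75_25(self):
        rng = np.random.default_rng(3)
        labels = np.repeat(list("abcd"), 10)
        table = tc.FeatureTable(
            matrix=pd.DataFrame({"x": rng.normal(size=40)})
        )
        res = classify_trials(table, labels, seed=0, n_estimators=10)
        assert (res.n_train, res.n_test) == (30, 10)

    def test_permuted_labels_accuracy_near_chance(self):
        # 4 balanced classes, label-independent features: the test accuracy
        # over many splits must fall in the 95% binomial band around 25%
        rng = np.random.default_rng(4)
        n = 160
        labels = rng.permutation(np.repeat(list("abcd"), n // 4))
        table = tc.FeatureTable(
            matrix=pd.DataFrame(rng.normal(size=(n, 5)),
                                columns=[f"f{i}" for i in range(5)])
        )
        correct = 0
        total = 0
        for seed in range(5):
            res = classify_trials(table, labels, seed=seed, n_estimators=50)
            correct += res.accuracy / 100.0 * res.n_test
            total += res.n_test
        p_hat = correct / total
        band = 1.96 * np.sqrt(0.25 * 0.75 / total)
        assert abs(p_hat - 0.25) <= band

    def test_confusion_rows_sum_to_100(self):
        rng = np.random.default_rng(5)
        labels = np.repeat(list("abc"), 12)
        table = tc.FeatureTable(matrix=pd.DataFrame({"x": rng.normal(size=36)}))
        res = classify_trials(table, labels, seed=1, n_estimators=20)
        sums = res.confusion.sum(axis=1).to_numpy()
        assert np.allclose(sums[sums > 0], 100.0, atol=0.1)

    def test_singleton_class_error_names_class(self):
        labels = np.array(["a"] * 10 + ["b"])
        table = tc.FeatureTable(matrix=pd.DataFrame({"x": np.arange(11.0)}))
        with pytest.raises(ValueError, match="'b'"):
            classify_trials(table, labels)


class TestPermutationImportance:
    def test_constant_attribute_importance_near_zero(self):
        rng = np.random.default_rng(6)
        n = 60
        labels = np.repeat(["a", "b"], n // 2)
        table = tc.FeatureTable(
            matrix=pd.DataFrame({
                "signal__m": np.where(labels == "a", 0, 4) + rng.normal(0, 1, n),
                "flat__m": np.ones(n),
            })
        )
        imp = permutation_importance(table, labels, repetitions=20,
                                     permutations=5, seed=0, n_estimators=30)
        assert abs(imp["flat"].mean()) < 0.01

    def test_informative_attribute_ranks_first(self):
        rng = np.random.default_rng(7)
        n = 60
        labels = np.repeat(["a", "b"], n // 2)
        cols = {"signal__m": np.where(labels == "a", 0.0, 4.0) + rng.normal(0, 0.5, n)}
        for i in range(3):
            cols[f"noise{i}__m"] = rng.normal(0, 1, n)
        table = tc.FeatureTable(matrix=pd.DataFrame(cols))
        imp = permutation_importance(table, labels, repetitions=20,
                                     permutations=5, seed=1, n_estimators=30)
        winners = imp.idxmax(axis=1)
        assert (winners == "signal").mean() >= 0.95

    def test_groups_columns_by_attribute(self):
        from touchcontact.features import _attribute_groups

        groups = _attribute_groups(["Vlg__mean", "Vlg__std", "area__mean", "duration"])
        assert groups == {"Vlg": ["Vlg__mean", "Vlg__std"],
                          "area": ["area__mean"], "duration": ["duration"]}


def mwu_oracle(x, y):
    """Pair-counting U for sample x: #{x_i > y_j} + 0.5 * ties."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


class TestCompareGestures:
    @staticmethod
    def _summaries(groups):
        rows = []
        for g, vals in groups.items():
            rows += [{"gesture": g, "Vlg": v} for v in vals]
        return pd.DataFrame(rows)

    def test_identical_groups_not_significant(self):
        vals = list(np.linspace(0, 1, 12))
        df = self._summaries({"hold": vals, "stroke": vals})
        out = compare_gestures(df, "Vlg")
        assert out.loc[0, "p"] > 0.9

    def test_fully_separated_groups_highly_significant(self):
        rng = np.random.default_rng(8)
        df = self._summaries(
            {"hold": rng.uniform(0, 1, 20), "stroke": rng.uniform(10, 11, 20)}
        )
        out = compare_gestures(df, "Vlg")
        assert out.loc[0, "p"] < 0.0001
        assert out.loc[0, "stars"] == "****"

    def test_u_statistic_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            nx, ny = rng.integers(3, 11, 2)
            x = rng.integers(0, 8, nx).astype(float)  # integer grid forces ties
            y = rng.integers(0, 8, ny).astype(float)
            df = self._summaries({"a": x, "b": y})
            out = compare_gestures(df, "Vlg")
            assert out.loc[0, "U"] == mwu_oracle(x, y)

    def test_small_group_error(self):
        df = self._summaries({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="fewer than 3"):
            compare_gestures(df, "Vlg")


def test_chance_levels_for_the_three_tasks():
    assert chance_level(4) == 25.0
    assert round(chance_level(7), 1) == 14.3
    assert chance_level(10) == 10.0
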