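"""Feature bank and random-forest branch.

The 11-statistic oracle below is coded directly from the defining
formulas (population moments, linear-interpolation percentiles) and is
kept independent of the implementation it checks.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from squatform import features, segment
from squatform.core import FORM_ORDER, SensorPlacement, SquatForm


def oracle_statistics(x):
    """Brute-force reference for the 11 statistics, from first principles."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    mean = sum(x) / n
    xs = sorted(x)
    median = (
        xs[n // 2] if n % 2 else (xs[n // 2 - 1] + xs[n // 2]) / 2
    )
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    sd = m2**0.5
    rms = (sum(v**2 for v in x) / n) ** 0.5
    skew = 0.0 if sd == 0 else m3 / m2**1.5
    kurt = 0.0 if sd == 0 else m4 / m2**2 - 3.0

    def pct(q):
        # linear interpolation between order statistics
        h = (n - 1) * q / 100.0
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return xs[lo] + (h - lo) * (xs[hi] - xs[lo])

    return np.array(
        [mean, median, max(x), min(x), sd, rms, max(x) - min(x),
         pct(25), pct(75), skew, kurt]
    )


class TestAxisStatistics:
    def test_matches_oracle_on_ramp(self):
        x = np.arange(1.0, 41.0)
        np.testing.assert_allclose(
            features.axis_statistics(x), oracle_statistics(x), rtol=1e-12
        )

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            x = rng.normal(scale=rng.uniform(0.1, 50), size=rng.integers(5, 80))
            got = features.axis_statistics(x)
            np.testing.assert_allclose(
                got, oracle_statistics(x), rtol=1e-9, atol=1e-12
            )

    def test_constant_axis_convention(self):
        got = features.axis_statistics(np.full(40, 3.0))
        expected = [3, 3, 3, 3, 0, 3, 0, 3, 3, 0, 0]
        np.testing.assert_allclose(got, expected, atol=1e-12)
        neg = features.axis_statistics(np.full(40, -2.0))
        assert neg[features.STAT_NAMES.index("rms")] == 2.0

    @given(
        st.lists(
            st.floats(-100, 100, allow_nan=False, width=32),
            min_size=3,
            max_size=60,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_order_invariants(self, xs):
        s = dict(zip(features.STAT_NAMES, features.axis_statistics(xs)))
        assert s["max"] >= s["median"] >= s["min"]
        assert s["p25"] <= s["median"] <= s["p75"]
        assert np.isclose(s["range"], s["max"] - s["min"])
        assert s["rms"] >= abs(s["mean"]) - 1e-9

    @given(
        st.lists(st.floats(-50, 50, allow_nan=False, width=32),
                 min_size=4, max_size=40),
        st.floats(0.1, 10.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_equivariance(self, xs, c):
        base = features.axis_statistics(xs)
        scaled = features.axis_statistics(np.asarray(xs) * c)
        linear = [i for i, n in enumerate(features.STAT_NAMES)
                  if n not in ("skewness", "kurtosis")]
        np.testing.assert_allclose(
            scaled[linear], base[linear] * c, rtol=1e-6, atol=1e-6
        )
        shape = [features.STAT_NAMES.index("skewness"),
                 features.STAT_NAMES.index("kurtosis")]
        np.testing.assert_allclose(scaled[shape], base[shape], rtol=1e-4, atol=1e-5)


class TestExtractFeatures:
    def test_single_placement_length_66(self, small_dataset):
        _, reps = small_dataset
        vec = features.extract_features(reps[0])
        assert vec.shape == (66,)

    def test_multi_placement_concatenation(self, small_multisensor_dataset):
        _, reps = small_multisensor_dataset
        vec = features.extract_features(reps[0])
        assert vec.shape == (5 * 66,)
        two = features.extract_features(
            reps[0], [SensorPlacement.RIGHT_THIGH, SensorPlacement.LUMBAR]
        )
        assert two.shape == (132,)
        # fixed site order: lumbar block first regardless of request order
        lum = features.extract_features(reps[0], [SensorPlacement.LUMBAR])
        np.testing.assert_array_equal(two[:66], lum)

    def test_wrong_shape_errors(self):
        rep = segment.Repetition(
            1, SquatForm.ACC, {SensorPlacement.LUMBAR: np.zeros((5, 40))}
        )
        with pytest.raises(ValueError):
            features.extract_features(rep)

    def test_feature_names_align(self, small_dataset):
        _, reps = small_dataset
        names = features.feature_names([SensorPlacement.RIGHT_THIGH])
        assert len(names) == 66
        assert names[0] == "right_thigh_ax_mean"
        assert names[-1] == "right_thigh_gz_kurtosis"
        df = features.feature_table(reps[:5])
        assert list(df.columns[3:]) == names


def _toy_clusters(n_per=20, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.normal(loc, 0.2, size=(n_per, 4)) for loc in (0.0, 5.0)]
    )
    y = np.array(["ACC"] * n_per + ["HS"] * n_per)
    return X, y


class TestForest:
    def test_separable_clusters_perfect_training_accuracy(self):
        X, y = _toy_clusters()
        model = features.train_forest(X, y, features.ForestConfig(50, None, 0))
        pred = np.argmax(features.predict_forest(model, X), axis=1)
        labels = np.array([FORM_ORDER.index(SquatForm(v)) for v in y])
        assert np.array_equal(pred, labels)

    def test_deterministic_given_seed(self):
        X, y = _toy_clusters()
        p1 = features.predict_forest(
            features.train_forest(X, y, features.ForestConfig(20, None, 5)), X
        )
        p2 = features.predict_forest(
            features.train_forest(X, y, features.ForestConfig(20, None, 5)), X
        )
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_errors(self):
        X = np.zeros((10, 3))
        with pytest.raises(ValueError, match="2 classes"):
            features.train_forest(X, ["ACC"] * 10)

    def test_probabilities_sum_to_one(self):
        X, y = _toy_clusters()
        model = features.train_forest(X, y, features.ForestConfig(30, None, 1))
        proba = features.predict_forest(model, np.random.default_rng(0).normal(size=(7, 4)))
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_feature_length_mismatch_errors(self):
        X, y = _toy_clusters()
        model = features.train_forest(X, y, features.ForestConfig(10, None, 0))
        with pytest.raises(ValueError, match="feature length"):
            features.predict_forest(model, np.zeros((2, 9)))

    def test_two_tree_votes_match_manual_trace(self):
        # tiny fixture: follow each tree's node arrays by hand and
        # average the two votes; must equal predict_forest's output
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 1, (4, 2)), rng.normal(4, 1, (4, 2))])
        y = ["KVG"] * 4 + ["KVR"] * 4
        model = features.train_forest(X, y, features.ForestConfig(2, None, 9))

        def trace(tree, x):
            node = 0
            while tree.children_left[node] != -1:
                if x[tree.feature[node]] <= tree.threshold[node]:
                    node = tree.children_left[node]
                else:
                    node = tree.children_right[node]
            counts = tree.value[node][0]
            return counts / counts.sum()

        for x in X:
            votes = np.mean(
                [trace(est.tree_, x) for est in model.estimators_], axis=0
            )
            expected = np.zeros(6)
            for j, cls in enumerate(model.classes_):
                expected[[f.value for f in FORM_ORDER].index(cls)] = votes[j]
            got = features.predict_forest(model, x[None])[0]
            np.testing.assert_allclose(got, expected, atol=1e-12)
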