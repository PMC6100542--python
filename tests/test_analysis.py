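"""Ground-state classification, slope fits, extrapolation, distances, tree, baselines."""

import numpy as np
import pytest

from octaspin.analysis import (
    baseline_fit,
    build_classification_tree,
    classify_ground_state,
    descriptor_distance,
    extrapolate_delta_ml,
    fit_sensitivity,
)


class TestGroundState:
    @pytest.mark.parametrize(
        "value, label",
        [(-54.2, "high"), (90.7, "low"), (0.0, "near-degenerate"),
         (-4.9, "near-degenerate"), (5.1, "low")],
    )
    def test_labels(self, value, label):
        assert classify_ground_state(value) == label

    def test_nonfinite_raises(self):
        with pytest.raises(ValueError):
            classify_ground_state(float("nan"))


class TestSensitivityFit:
    def test_exact_line(self):
        a = np.array([0.0, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3])
        e = 12.0 - 100.0 * a
        fit = fit_sensitivity(a, e)
        assert fit.slope == pytest.approx(-100.0)
        assert fit.intercept == pytest.approx(12.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_two_points_closed_form(self):
        fit = fit_sensitivity([0.0, 0.2], [10.0, 4.0])
        assert fit.slope == pytest.approx((4.0 - 10.0) / 0.2)
        assert fit.r_squared == pytest.approx(1.0)

    def test_noisy_recovery_within_two_se(self):
        rng = np.random.default_rng(17)
        a = np.array([0.0, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3])
        true_slope = -120.0
        for _ in range(20):
            e = 5.0 + true_slope * a + rng.normal(scale=1.0, size=a.size)
            fit = fit_sensitivity(a, e)
            assert abs(fit.slope - true_slope) <= 4 * fit.stderr  # 2 SE each-way slack

    def test_insufficient_points_raise(self):
        with pytest.raises(ValueError):
            fit_sensitivity([0.2], [1.0])
        with pytest.raises(ValueError):
            fit_sensitivity([0.2, 0.2], [1.0, 2.0])


class TestExtrapolation:
    def test_zero_slope_identity(self):
        assert extrapolate_delta_ml(7.3, 0.0, 0.0, 0.2) == pytest.approx(7.3)

    def test_arithmetic(self):
        assert extrapolate_delta_ml(10.0, -100.0, 0.0, 0.20) == pytest.approx(-10.0)

    def test_round_trip_to_source_exact(self):
        assert extrapolate_delta_ml(3.7, -55.0, 0.1, 0.1) == 3.7

    def test_consistency_with_fitted_slope(self):
        a = np.array([0.0, 0.1, 0.2, 0.3])
        e = 8.0 - 60.0 * a
        fit = fit_sensitivity(a, e)
        assert extrapolate_delta_ml(e[0], fit.slope, 0.0, 0.3) == pytest.approx(e[-1])


class TestDescriptorDistance:
    def test_training_point_distance_zero(self):
        rng = np.random.default_rng(0)
        T = rng.normal(size=(30, 8))
        report = descriptor_distance(T[:5], T)
        np.testing.assert_allclose(report.euclidean, 0.0, atol=1e-12)
        assert not report.flagged.any()

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(1)
        T = rng.normal(size=(40, 6))
        Q = rng.normal(size=(15, 6))
        report = descriptor_distance(Q, T)
        for i, q in enumerate(Q):
            dists = np.linalg.norm(T - q, axis=1)
            assert report.euclidean[i] == pytest.approx(dists.min())
            assert report.nearest_index[i] == np.argmin(dists)
            cos = (T @ q) / (np.linalg.norm(T, axis=1) * np.linalg.norm(q))
            assert report.uncentered_pearson[i] == pytest.approx(1.0 - cos.max())

    def test_threshold_flagging(self):
        T = np.zeros((3, 4))
        q = np.zeros((1, 4))
        q[0, 0] = 1.4
        report = descriptor_distance(q, T, threshold=1.0)
        assert report.flagged[0]

    def test_encoding_mismatch_raises(self):
        with pytest.raises(ValueError, match="encoding"):
            descriptor_distance(np.zeros((2, 3)), np.zeros((2, 4)))


class TestClassificationTree:
    def test_perfectly_separable_single_split(self):
        X = np.concatenate([np.full(30, -1.0), np.full(30, 1.0)]).reshape(-1, 1)
        y = ["high"] * 30 + ["low"] * 30
        tree = build_classification_tree(X, y, ["field"], max_splits=6, min_leaf=10)
        assert len(tree.leaves) == 2
        assert all(leaf.purity == 1.0 for leaf in tree.leaves)

    def test_leaves_partition_population(self, small_synth):
        from octaspin.descriptors import featurize_many
        from octaspin.encoding import encode
        from octaspin.io import extract_target

        specs, y = extract_target(small_synth.table, "splitting")
        labels = ["high" if e < 0 else "low" for e in y]
        X, meta = encode(featurize_many(specs, set_id="g"), mode="ann")
        tree = build_classification_tree(X, labels, meta.column_names)
        shares = [leaf.population_share for leaf in tree.leaves]
        counts = [leaf.n for leaf in tree.leaves]
        assert sum(counts) == len(labels)
        assert sum(shares) == pytest.approx(1.0)
        assert len(tree.leaves) <= 7  # at most max_splits divisions
        assert all(leaf.n >= 10 for leaf in tree.leaves)

    def test_greedy_split_is_impurity_optimal(self):
        """The root split matches exhaustive enumeration of candidate splits."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(80, 3))
        y = np.where(X[:, 1] + 0.3 * rng.normal(size=80) > 0.2, "low", "high")
        tree = build_classification_tree(X, list(y), ["f0", "f1", "f2"], max_splits=1, min_leaf=10)

        def gini(labels):
            if len(labels) == 0:
                return 0.0
            p = np.mean(labels == "low")
            return 1.0 - p**2 - (1 - p) ** 2

        best = np.inf
        for j in range(3):
            for thr in np.unique(X[:, j]):
                left, right = y[X[:, j] <= thr], y[X[:, j] > thr]
                if len(left) < 10 or len(right) < 10:
                    continue
                score = (len(left) * gini(left) + len(right) * gini(right)) / len(y)
                best = min(best, score)
        t = tree.estimator.tree_
        feat, thr = t.feature[0], t.threshold[0]
        left = y[X[:, feat] <= thr]
        right = y[X[:, feat] > thr]
        achieved = (len(left) * gini(left) + len(right) * gini(right)) / len(y)
        assert achieved == pytest.approx(best, abs=1e-12)

    def test_strong_field_carbon_root_split(self, small_synth):
        """On homoleptic synthetic data the root division separates C-coordinating
        (strong-field, low-spin-favoring) complexes, echoing the spectrochemical series."""
        from octaspin.descriptors import featurize_many
        from octaspin.encoding import encode
        from octaspin.io import extract_target

        df = small_synth.table.df
        homoleptic = df[df.eq_ligand == df.ax_ligand]
        if len(homoleptic) < 60:  # fall back to the full table if the draw is small
            homoleptic = df
        from octaspin.io import DatasetTable

        sub = DatasetTable(df=homoleptic.reset_index(drop=True), library=small_synth.table.library)
        specs, y = extract_target(sub, "splitting")
        labels = ["high" if e < 0 else "low" for e in y]
        X, meta = encode(featurize_many(specs, set_id="g"), mode="ann")
        tree = build_classification_tree(X, labels, meta.column_names)
        root_feature = meta.column_names[tree.estimator.tree_.feature[0]]
        assert root_feature in {"L_eq=C", "L_ax=C", "me", "se", "b_eq", "b_ax"}

    def test_empty_data_raises(self):
        with pytest.raises(ValueError):
            build_classification_tree(np.empty((0, 2)), [], ["a", "b"])


class TestBaselines:
    def test_krr_matches_closed_form(self):
        """KRR prediction equals (K + alpha I)^-1 y with the RBF kernel on a toy set."""
        from sklearn.metrics.pairwise import rbf_kernel

        X = np.array([[0.0], [0.5], [1.0], [1.5], [2.0]])
        y = np.array([0.0, 0.4, 1.1, 0.7, -0.2])
        gamma, alpha = 0.8, 0.05
        result = baseline_fit(
            X, y, method="krr",
            gamma_grid=(gamma,), reg_grid=(alpha,),
            folds=2, split_fraction=0.999,
        )
        K = rbf_kernel(X, X, gamma=gamma)
        weights = np.linalg.solve(K + alpha * np.eye(len(X)), y)
        expected = rbf_kernel(X, X, gamma=gamma) @ weights
        np.testing.assert_allclose(result.predict(X), expected, atol=1e-8)

    def test_zero_noise_near_interpolation(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 3))
        y = np.sin(X[:, 0]) + X[:, 1] ** 2
        result = baseline_fit(
            X, y, method="krr", gamma_grid=(0.5,), reg_grid=(1e-9,),
            folds=2, split_fraction=0.999,
        )
        assert result.train_rmse < 1e-3

    @pytest.mark.parametrize("method", ["krr", "svr"])
    def test_comparative_harness_shape(self, small_splitting, method):
        from octaspin.descriptors import featurize_many
        from octaspin.encoding import encode

        specs, y = small_splitting
        X, _ = encode(featurize_many(list(specs), set_id="g"), mode="ann")
        result = baseline_fit(
            X, y, method=method,
            gamma_grid=(1e-2, 1e-1), reg_grid=(1e-3, 1e-1), epsilon_grid=(0.1,),
            folds=5,
        )
        assert result.method == method
        assert np.isfinite(result.train_rmse) and np.isfinite(result.test_rmse)
        assert result.test_rmse >= 0 and result.train_max_ue >= 0
        assert len(result.train_indices) + len(result.test_indices) == len(y)

    def test_unknown_method_raises(self):
        with pytest.raises(ValueError):
            baseline_fit(np.zeros((10, 2)), np.zeros(10), method="rf")
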