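"""PLS-DA, cross-validation and Clarke error grid, checked against
independent oracles (ordinary least squares, scikit-learn's PLS)."""


import numpy as np
import pytest

from pztpas.chemometrics import (
    clarke_zone,
    clarke_zones,
    fit_pls,
    kfold_accuracy,
    label_by_threshold,
    posterior_to_glucose,
    predict_class,
    predict_posterior,
    predict_response,
    q2_loo,
    run_experiment,
)


class TestLabelByThreshold:
    @pytest.mark.parametrize(("g", "expected"), [(139.0, 0), (140.0, 0), (141.0, 1)])
    def test_threshold_rule(self, g, expected):
        assert label_by_threshold(g) == expected

    def test_vectorized_preserves_order(self):
        g = np.array([100.0, 150.0, 140.0, 200.0])
        np.testing.assert_array_equal(label_by_threshold(g), [0, 1, 0, 1])

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            label_by_threshold(0.0)


class TestFitPls:
    def test_single_component_weight_is_normalized_covariance(self, rng):
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        model = fit_pls(X, y, 1)
        Xc = X - X.mean(axis=0)
        w = Xc.T @ (y - y.mean())
        np.testing.assert_allclose(model.weights[:, 0], w / np.linalg.norm(w), rtol=1e-10)

    def test_full_rank_equals_least_squares(self, rng):
        """With as many latent variables as the rank of X, PLS reproduces the
        ordinary least-squares fit (100 random 10x3 instances)."""
        for _ in range(100):
            X = rng.normal(size=(10, 3))
            y = rng.normal(size=10)
            model = fit_pls(X, y, 3)
            pred = predict_response(model, X)
            Xc = np.column_stack([np.ones(10), X])
            beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
            ols = Xc @ beta
            np.testing.assert_allclose(pred, ols, rtol=1e-6, atol=1e-6)

    def test_matches_sklearn_pls_predictions(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(30, 8))
        y = rng.normal(size=30)
        for k in (1, 2, 4):
            model = fit_pls(X, y, k)
            ref = sklearn.PLSRegression(n_components=k, scale=False).fit(X, y)
            np.testing.assert_allclose(
                predict_response(model, X), ref.predict(X).ravel(), rtol=1e-8, atol=1e-8)

    def test_score_orthogonality(self, rng):
        X = rng.normal(size=(40, 10))
        y = rng.normal(size=40)
        model = fit_pls(X, y, 5)
        Xc = X - model.x_mean
        # reconstruct scores by running deflation forward
        scores = []
        Xd = Xc.copy()
        for a in range(model.n_latent):
            t = Xd @ model.weights[:, a]
            scores.append(t)
            Xd = Xd - np.outer(t, model.x_loadings[:, a])
        T = np.column_stack(scores)
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() <= 1e-8 * np.abs(np.diag(G)).max()

    def test_duplicated_samples_leave_regression_vector_unchanged(self, rng):
        X = rng.normal(size=(12, 4))
        y = rng.normal(size=12)
        m1 = fit_pls(X, y, 2)
        m2 = fit_pls(np.vstack([X, X]), np.concatenate([y, y]), 2)
        np.testing.assert_allclose(m1.regression_vector, m2.regression_vector, rtol=1e-8)

    def test_n_latent_above_rank_rejected(self, rng):
        X = rng.normal(size=(5, 3))
        with pytest.raises(ValueError):
            fit_pls(X, rng.normal(size=5), 4)

    def test_constant_y_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_pls(rng.normal(size=(6, 3)), np.ones(6), 1)


class TestPosterior:
    def test_clipped_to_unit_interval(self, rng):
        X = rng.normal(size=(15, 3))
        y = (rng.normal(size=15) > 0).astype(float)
        model = fit_pls(X, y, 2)
        post = predict_posterior(model, rng.normal(size=(50, 3)) * 10)
        assert post.min() >= 0.0 and post.max() <= 1.0

    def test_separable_training_data_classified_correctly(self, noiseless_dataset):
        from pztpas.preprocess import preprocess_dataset
        X, y, _, _ = preprocess_dataset(noiseless_dataset)
        model = fit_pls(X, y.astype(float), 2)
        np.testing.assert_array_equal(predict_class(model, X), y)

    def test_feature_count_mismatch_rejected(self, rng):
        X = rng.normal(size=(10, 4))
        model = fit_pls(X, rng.normal(size=10), 2)
        with pytest.raises(ValueError):
            predict_posterior(model, np.zeros((3, 5)))


class TestPosteriorToGlucose:
    @pytest.mark.parametrize(("p", "expected"), [(0.0, 95.0), (1.0, 185.0),
                                                 (0.5, 140.0), (0.25, 117.5)])
    def test_linear_map(self, p, expected):
        assert posterior_to_glucose(p) == expected

    def test_midpoint_is_exactly_class_threshold(self):
        assert posterior_to_glucose(0.5) == 140.0

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            posterior_to_glucose(1.2)


class TestQ2Loo:
    def test_strong_signal_reaches_high_q2(self, noiseless_dataset):
        from pztpas.preprocess import preprocess_dataset
        X, y, _, _ = preprocess_dataset(noiseless_dataset)
        report = q2_loo(X, y.astype(float))
        assert max(report.q2_per_lv) > 0.9

    def test_q2_bounded_above_by_one(self, rng):
        X = rng.normal(size=(25, 6))
        y = rng.normal(size=25)
        report = q2_loo(X, y)
        assert all(q <= 1.0 for q in report.q2_per_lv)

    def test_chosen_lv_is_first_argmax(self, rng):
        X = rng.normal(size=(25, 6))
        y = X[:, 0] * 2.0 + 0.01 * rng.normal(size=25)
        report = q2_loo(X, y)
        best = max(report.q2_per_lv)
        assert report.q2_per_lv[report.chosen_lv - 1] == best
        assert all(q < best for q in report.q2_per_lv[: report.chosen_lv - 1])

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            q2_loo(rng.normal(size=(2, 3)), np.array([0.0, 1.0]))


class TestKfoldAccuracy:
    def test_noiseless_data_scores_near_perfectly(self, noiseless_dataset):
        """Zero-noise spectra are in-sample separable; cross-validated accuracy
        can still drop a sample whose glucose sits arbitrarily close to the
        140 mg/dL threshold (vanishing margin), so the bound is 0.95."""
        from pztpas.preprocess import preprocess_dataset
        X, y, _, _ = preprocess_dataset(noiseless_dataset)
        report = kfold_accuracy(X, y, n_latent=2, seed=0)
        assert report.mean_accuracy >= 0.95

    def test_null_features_score_near_chance(self, rng):
        accs = []
        for seed in range(20):
            local = np.random.default_rng(seed)
            X = local.normal(size=(60, 10))
            y = np.repeat([0, 1], 30)
            accs.append(kfold_accuracy(X, y, n_latent=2, seed=seed).mean_accuracy)
        assert 0.35 <= np.mean(accs) <= 0.65

    def test_folds_are_seed_reproducible(self, fixed_dataset):
        from pztpas.preprocess import preprocess_dataset
        X, y, _, _ = preprocess_dataset(fixed_dataset)
        a = kfold_accuracy(X, y, n_latent=3, seed=5)
        b = kfold_accuracy(X, y, n_latent=3, seed=5)
        assert a.fold_accuracies == b.fold_accuracies


class TestClarkeGrid:
    @pytest.mark.parametrize(
        ("ref", "pred", "zone"),
        [
            (100.0, 100.0, "A"),   # zero error
            (65.0, 65.0, "A"),     # both-below-70 square
            (100.0, 119.0, "A"),   # within 20 %
            (190.0, 65.0, "E"),    # hyper read as hypo
            (65.0, 185.0, "E"),    # hypo read as hyper
            (100.0, 215.0, "C"),   # overcorrection upper
            (160.0, 40.0, "C"),    # overcorrection lower
            (300.0, 100.0, "D"),   # missed hyperglycemia
            (50.0, 120.0, "D"),    # missed hypoglycemia
            (200.0, 150.0, "B"),   # benign error
        ],
    )
    def test_zone_geometry(self, ref, pred, zone):
        assert clarke_zone(ref, pred) == zone

    def test_total_partition_on_lattice(self):
        """Every (reference, predicted) pair on a 1-mg/dL lattice over
        (0, 400]^2 receives exactly one zone."""
        g = np.arange(1.0, 401.0)
        ref, pred = np.meshgrid(g, g, indexing="ij")
        zones = clarke_zones(ref, pred)
        assert zones.shape == ref.shape
        assert set(np.unique(zones)) <= set("ABCDE")

    def test_zone_a_symmetric_only_in_relative_band(self):
        # inside the 20 % band symmetry holds ...
        assert clarke_zone(100.0, 115.0) == clarke_zone(115.0, 100.0) == "A"
        # ... but the grid as a whole is asymmetric under ref <-> pred
        assert clarke_zone(300.0, 150.0) == "D"
        assert clarke_zone(150.0, 300.0) == "C"

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            clarke_zone(0.0, 100.0)
        with pytest.raises(ValueError):
            clarke_zone(100.0, 700.0)


class TestRunExperiment:
    def test_noiseless_dataset_is_near_perfect_and_clinically_accurate(self, noiseless_dataset):
        report = run_experiment(noiseless_dataset, seed=0)
        assert report["mean_accuracy"] >= 0.95
        assert all(z in ("A", "B") for z in report["clarke_zones"])

    def test_report_is_seed_deterministic(self, fixed_dataset):
        a = run_experiment(fixed_dataset, seed=3)
        b = run_experiment(fixed_dataset, seed=3)
        assert a == b
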