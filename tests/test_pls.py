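"""The PLS score classifier: closed-form weights, threshold selection,
scoring and sklearn-estimator behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import plsnet as P
from plsnet.pls import HubScoreClassifier, select_threshold


def closed_form_weights(X, y):
    """Independent oracle: w proportional to Xs^T y_c on standardized X."""
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    yc = y - y.mean()
    w = Xs.T @ yc
    return w / np.linalg.norm(w)


def make_xy(rng, n=40, p=5, effect=None):
    y = np.array([1] * (n // 2) + [0] * (n - n // 2))
    X = rng.normal(size=(n, p))
    if effect is not None:
        X[:, 0] += effect * y
    return X, y


class TestWeights:
    def test_label_aligned_gene_gets_all_weight(self):
        rng = np.random.default_rng(0)
        n = 400
        y = np.array([1] * (n // 2) + [0] * (n // 2))
        g1 = (y - y.mean()) / np.std(y, ddof=1)  # standardized label pattern
        noise = rng.normal(size=n)
        noise -= noise.mean() + (noise @ (y - y.mean())) / ((y - y.mean()) @ (y - y.mean())) * (y - y.mean())
        X = np.column_stack([g1, noise])
        est = HubScoreClassifier().fit(X, y)
        assert abs(est.weights_[0]) == pytest.approx(1.0, abs=1e-6)
        assert abs(est.weights_[1]) == pytest.approx(0.0, abs=1e-6)

    def test_duplicated_predictor_splits_weight_equally(self):
        rng = np.random.default_rng(1)
        X, y = make_xy(rng, effect=2.0)
        X2 = np.column_stack([X[:, 0], X[:, 0]])
        est = HubScoreClassifier().fit(X2, y)
        assert est.weights_ == pytest.approx([1 / np.sqrt(2)] * 2, abs=1e-12)

    def test_weights_unit_norm(self):
        rng = np.random.default_rng(2)
        X, y = make_xy(rng, effect=1.0)
        est = HubScoreClassifier().fit(X, y)
        assert np.linalg.norm(est.weights_) == pytest.approx(1.0, abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_one_component_fit_equals_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 30)) * 2
        p = int(rng.integers(1, 8))
        X, y = make_xy(rng, n=n, p=p, effect=1.5)
        est = HubScoreClassifier(n_components=1).fit(X, y)
        np.testing.assert_allclose(est.weights_, closed_form_weights(X, y), atol=1e-10)

    def test_multicomponent_matches_sklearn_pls_direction(self):
        # independent cross-check of the NIPALS collapse against sklearn
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(3)
        X, y = make_xy(rng, n=60, p=6, effect=2.0)
        est = HubScoreClassifier(n_components=3).fit(X, y)
        ref = PLSRegression(n_components=3, scale=True).fit(X, y.astype(float))
        # sklearn reports coefficients on the raw scale; undo that to compare
        # directions in standardized space
        raw = ref.coef_.ravel() * X.std(axis=0, ddof=1)
        ref_w = raw / np.linalg.norm(raw)
        sign = np.sign(ref_w @ est.weights_)
        np.testing.assert_allclose(est.weights_, sign * ref_w, atol=1e-8)

    def test_zero_variance_predictor_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        X, y = make_xy(rng, effect=2.0)
        X[:, 3] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            est = HubScoreClassifier().fit(X, y)
        assert est.weights_[3] == 0.0

    def test_all_zero_variance_errors(self):
        X = np.full((10, 3), 2.0)
        y = np.array([1] * 5 + [0] * 5)
        with pytest.raises(ValueError):
            HubScoreClassifier().fit(X, y)

    def test_too_many_components_errors(self):
        rng = np.random.default_rng(5)
        X, y = make_xy(rng, n=10, p=3)
        with pytest.raises(ValueError, match="n_components"):
            HubScoreClassifier(n_components=4).fit(X, y)


class TestThreshold:
    def test_separable_midpoint(self):
        theta = select_threshold([2, 3, 0, 1], [1, 1, 0, 0])
        assert theta == pytest.approx(1.5)

    def test_all_equal_scores_degenerate(self):
        theta = select_threshold([1.0, 1.0, 1.0, 1.0], [1, 1, 0, 0])
        assert theta < 1.0  # sentinel below min: everything called case

    def test_interleaved_matches_bruteforce(self):
        scores = np.array([1.0, 3.0, 2.0, 4.0])
        labels = np.array([1, 1, 0, 0])
        theta = select_threshold(scores, labels)

        def youden(cut):
            pred = scores >= cut
            sens = (pred & (labels == 1)).sum() / 2
            spec = (~pred & (labels == 0)).sum() / 2
            return sens + spec - 1

        grid = np.concatenate([[0.0], (np.unique(scores)[:-1] + np.unique(scores)[1:]) / 2, [5.0]])
        best = max(youden(c) for c in grid)
        assert youden(theta) == pytest.approx(best)
        # ties broken by the smallest candidate
        assert theta == min(c for c in grid if youden(c) == best)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_selected_threshold_maximizes_youden(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        labels = np.concatenate([[1, 0], rng.integers(0, 2, n - 2)])
        scores = np.round(rng.normal(size=n), 1)  # induce ties
        theta = select_threshold(scores, labels)
        n1, n0 = (labels == 1).sum(), (labels == 0).sum()

        def youden(cut):
            pred = scores >= cut
            return ((pred & (labels == 1)).sum() / n1
                    + (~pred & (labels == 0)).sum() / n0 - 1)

        grid = np.concatenate([[scores.min() - 1],
                               np.unique(scores),
                               (np.unique(scores)[:-1] + np.unique(scores)[1:]) / 2
                               if len(np.unique(scores)) > 1 else [],
                               [scores.max() + 1]])
        assert youden(theta) >= max(youden(c) for c in grid) - 1e-12

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            select_threshold([1, 2], [1, 1])


class TestScoringAndClassification:
    def test_training_means_score_zero(self, separable7):
        ds, _, truth = separable7
        model = P.fit(ds, truth.hub_genes)
        centered = ds.restrict(list(truth.hub_genes))
        centered.values.iloc[:, :] = np.tile(
            model.center[:, None], (1, ds.n_samples)
        )
        np.testing.assert_allclose(P.compute_scores(model, centered), 0.0, atol=1e-12)

    def test_scores_invariant_to_gene_row_order(self, separable7):
        ds, _, truth = separable7
        model = P.fit(ds, truth.hub_genes)
        shuffled = P.ExpressionDataset(ds.values.iloc[::-1], ds.labels)
        np.testing.assert_allclose(
            P.compute_scores(model, ds), P.compute_scores(model, shuffled)
        )

    def test_missing_model_gene_errors(self, separable7):
        ds, _, truth = separable7
        model = P.fit(ds, truth.hub_genes)
        reduced = ds.restrict([g for g in ds.gene_ids if g != "I1"])
        with pytest.raises(KeyError, match="I1"):
            P.compute_scores(model, reduced)

    def test_boundary_score_equal_threshold_is_case(self):
        rng = np.random.default_rng(6)
        X, y = make_xy(rng, effect=3.0)
        est = HubScoreClassifier().fit(X, y)
        s = est.score_samples(X)
        # synthetic scores straddling theta
        eps = 1e-9
        theta = est.threshold_
        fake = np.array([theta - eps, theta, theta + eps])
        assert list(fake >= theta) == [False, True, True]

    def test_scale_equivariance(self, separable7):
        ds, _, truth = separable7
        model_a = P.fit(ds, truth.hub_genes)
        scaled = P.ExpressionDataset(ds.values * 1.0, ds.labels)
        scaled.values.loc["I1"] *= 10
        model_b = P.fit(scaled, truth.hub_genes)
        np.testing.assert_allclose(
            P.compute_scores(model_a, ds), P.compute_scores(model_b, scaled), atol=1e-9
        )

    def test_empty_sample_set_classifies_empty(self, separable7):
        ds, _, truth = separable7
        model = P.fit(ds, truth.hub_genes)
        empty = ds.subset_samples([])
        assert P.compute_scores(model, empty).size == 0

    def test_held_out_half_of_separable_fixture_perfect(self, separable7):
        ds, _, truth = separable7
        train = ds.subset_samples(list(range(0, 10)) + list(range(20, 30)))
        test = ds.subset_samples(list(range(10, 20)) + list(range(30, 40)))
        model = P.fit(train, truth.hub_genes)
        assert (P.classify(model, test) == test.labels).all()

    def test_fit_deterministic(self, paperlike):
        ds, _, truth = paperlike
        a = P.fit(ds, truth.hub_genes)
        b = P.fit(ds, truth.hub_genes)
        np.testing.assert_array_equal(a.weights, b.weights)
        assert a.threshold == b.threshold

    def test_model_json_roundtrip(self, tmp_path, separable7):
        ds, _, truth = separable7
        model = P.fit(ds, truth.hub_genes)
        path = tmp_path / "model.json"
        model.save(path)
        back = P.PLSModel.load(path)
        np.testing.assert_array_equal(back.weights, model.weights)
        np.testing.assert_allclose(
            P.compute_scores(back, ds), P.compute_scores(model, ds)
        )


class TestSklearnCompat:
    def test_clone_and_get_params(self):
        from sklearn.base import clone

        est = HubScoreClassifier(n_components=2)
        assert clone(est).get_params() == {"n_components": 2}

    def test_works_in_pipeline_with_selector(self, paperlike):
        from sklearn.pipeline import make_pipeline

        from plsnet.diffexp import TTestFDRSelector

        ds, _, _ = paperlike
        pipe = make_pipeline(TTestFDRSelector(0.05), HubScoreClassifier())
        pipe.fit(ds.X, ds.y)
        assert pipe.score(ds.X, ds.y) > 0.9

    def test_arbitrary_class_labels(self):
        rng = np.random.default_rng(7)
        X, y01 = make_xy(rng, effect=3.0)
        y = np.where(y01 == 1, "tumor", "normal")
        est = HubScoreClassifier().fit(X, y)
        assert set(est.predict(X)) <= {"tumor", "normal"}
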