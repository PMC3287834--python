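"""PLS1 gene collapsing: weights, deflation, CV sizing, macrovariant scoring."""

import numpy as np
import pytest

from macrovar.pls_collapse import (
    cv_select_ncomp,
    fit_pls1,
    predict_pls1,
    score_macrovariants,
)


def centered(X):
    return X - X.mean(axis=0)


class TestFitPls1:
    def test_single_column_weight_is_unit(self, rng):
        x = centered(rng.normal(size=(40, 1)))
        y = x[:, 0] + 0.1 * rng.normal(size=40)
        m = fit_pls1(y, x, 1)
        assert m.n_components == 1
        assert abs(m.weights[0, 0]) == pytest.approx(1.0)
        np.testing.assert_allclose(
            m.weights[0, 0] * x[:, 0],
            score_macrovariants(m, x)[0].scores,
            atol=1e-12,
        )

    def test_orthogonal_response_yields_no_components(self, rng):
        X = centered(rng.normal(size=(30, 4)))
        y = rng.normal(size=30)
        y = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]  # exactly orthogonal
        m = fit_pls1(y, X, 3)
        assert m.n_components == 0

    def test_duplicate_columns_share_weight(self, rng):
        x = centered(rng.normal(size=(50, 1)))
        X = np.column_stack([x, x, centered(rng.normal(size=(50, 1)))])
        y = X @ [1.0, 1.0, 0.3] + 0.1 * rng.normal(size=50)
        m = fit_pls1(y, X, 1)
        assert m.weights[0, 0] == pytest.approx(m.weights[1, 0], rel=1e-12)

    def test_first_weight_proportional_to_cross_covariance(self, rng):
        X = centered(rng.normal(size=(60, 8)))
        y = X @ rng.normal(size=8) + rng.normal(size=60)
        m = fit_pls1(y - y.mean(), X, 3)
        v = X.T @ (y - y.mean())
        cos = abs(v @ m.weights[:, 0]) / np.linalg.norm(v)
        assert cos == pytest.approx(1.0, abs=1e-12)

    def test_training_scores_mutually_orthogonal(self, rng):
        X = centered(rng.normal(size=(80, 12)))
        y = X @ rng.normal(size=12) + rng.normal(size=80)
        m = fit_pls1(y, X, 5)
        T = np.column_stack([mv.scores for mv in score_macrovariants(m, X)])
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() <= 1e-8 * np.abs(np.diag(G)).max()

    def test_scale_equivariance_in_y(self, rng):
        X = centered(rng.normal(size=(40, 6)))
        y = X @ rng.normal(size=6) + rng.normal(size=40)
        m1 = fit_pls1(y, X, 3)
        m2 = fit_pls1(7.0 * y, X, 3)
        np.testing.assert_allclose(m1.weights, m2.weights, atol=1e-10)

    def test_sign_convention_largest_entry_positive(self, rng):
        X = centered(rng.normal(size=(40, 6)))
        y = X @ rng.normal(size=6)
        m = fit_pls1(y, X, 2)
        for c in range(m.n_components):
            w = m.weights[:, c]
            assert w[np.argmax(np.abs(w))] > 0

    def test_zero_variance_gene_gives_zero_components(self):
        X = np.zeros((20, 3))
        y = np.linspace(-1, 1, 20)
        assert fit_pls1(y, X, 2).n_components == 0

    def test_matches_sklearn_pls_predictions(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(60, 10))
        y = X @ rng.normal(size=10) + rng.normal(size=60)
        k = 3
        m = fit_pls1(y, X, k)
        ours = predict_pls1(m, X)
        ref = sklearn.PLSRegression(n_components=k, scale=False).fit(X, y)
        np.testing.assert_allclose(ours, ref.predict(X).ravel(), atol=1e-8)


class TestScoring:
    def test_scoring_training_matrix_is_idempotent(self, rng):
        X = rng.normal(size=(50, 7))
        y = X @ rng.normal(size=7) + rng.normal(size=50)
        m = fit_pls1(y, X, 3)
        first = [mv.scores.copy() for mv in score_macrovariants(m, X)]
        second = [mv.scores for mv in score_macrovariants(m, X)]
        for a, b in zip(first, second):
            np.testing.assert_array_equal(a, b)

    def test_scores_have_mean_zero_on_training_data(self, rng):
        X = rng.normal(size=(50, 7)) + 3.0
        y = X @ rng.normal(size=7)
        m = fit_pls1(y, X, 2)
        for mv in score_macrovariants(m, X):
            assert abs(mv.scores.mean()) < 1e-10

    def test_zero_components_gives_empty_list(self):
        m = fit_pls1(np.linspace(-1, 1, 20), np.zeros((20, 3)), 2)
        assert score_macrovariants(m, np.zeros((20, 3))) == []

    def test_member_mismatch_is_error(self, rng):
        X = rng.normal(size=(30, 4))
        m = fit_pls1(X @ np.ones(4), X, 1, gene="G1")
        with pytest.raises(ValueError, match="G1"):
            score_macrovariants(m, X[:, :3])


class TestCvSelect:
    def test_null_gene_prefers_intercept_only(self, rng):
        zeros = 0
        runs = 30
        for s in range(runs):
            local = np.random.default_rng(1000 + s)
            X = local.binomial(2, 0.02, size=(200, 20)).astype(float)
            y = np.where(local.random(200) < 0.3, 1.0, -1.0)
            k, _ = cv_select_ncomp(y - y.mean(), centered(X), max_comp=5, seed=s)
            zeros += k == 0
        assert zeros >= 0.7 * runs

    def test_dense_signal_gene_selected(self, rng):
        hits = 0
        runs = 20
        for s in range(runs):
            local = np.random.default_rng(2000 + s)
            X = local.binomial(2, 0.05, size=(200, 20)).astype(float)
            y = X @ local.normal(1.0, 0.2, size=20) + 0.5 * local.normal(size=200)
            k, _ = cv_select_ncomp(y - y.mean(), centered(X), max_comp=5, seed=s)
            hits += k >= 1
        assert hits >= 0.95 * runs

    def test_single_variant_gene_bounded(self, rng):
        X = rng.binomial(2, 0.05, size=(100, 1)).astype(float)
        y = np.where(rng.random(100) < 0.3, 1.0, -1.0)
        k, errs = cv_select_ncomp(y, X, max_comp=1, seed=0)
        assert k in (0, 1)
        assert len(errs) == 2

    def test_too_few_individuals_is_error(self):
        with pytest.raises(ValueError, match="too small"):
            cv_select_ncomp(np.ones(6), np.ones((6, 2)), max_comp=1, folds=5)

    def test_seeded_determinism(self, rng):
        X = rng.normal(size=(100, 10))
        y = X @ rng.normal(size=10) + rng.normal(size=100)
        a = cv_select_ncomp(y, X, max_comp=4, seed=42)
        b = cv_select_ncomp(y, X, max_comp=4, seed=42)
        assert a[0] == b[0]
        np.testing.assert_array_equal(a[1], b[1])
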