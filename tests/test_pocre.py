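"""POCRE-LDA: sparse orthogonal components, back-mapping, classification."""

import numpy as np
import pytest

from macrovar.pocre import DEFAULT_LAMBDA_GRID, PocreLDA, fit_pocre


def signal_instance(seed, n=120, p=40, k=5, noise=0.5):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    X -= X.mean(axis=0)
    b = np.zeros(p)
    b[rng.choice(p, k, replace=False)] = rng.normal(2.0, 0.5, k)
    y = X @ b + noise * rng.normal(size=n)
    return y - y.mean(), X


class TestFitPocre:
    def test_lambda_out_of_range_rejected(self):
        y, X = signal_instance(0)
        for lam in (0.0, 1.0, -0.5, 1.5):
            with pytest.raises(ValueError, match="lam"):
                fit_pocre(y, X, lam)

    def test_uncentered_input_rejected(self):
        y, X = signal_instance(0)
        with pytest.raises(ValueError, match="centered"):
            fit_pocre(y, X + 5.0, 0.85)
        with pytest.raises(ValueError, match="centered"):
            fit_pocre(y + 5.0, X, 0.85)

    def test_component_orthogonality(self):
        for seed in range(5):
            y, X = signal_instance(seed, n=150, p=80, k=8)
            fit = fit_pocre(y, X, 0.85)
            if fit.n_components < 2:
                continue
            T = fit.scores
            G = T.T @ T
            off = np.abs(G - np.diag(np.diag(G))).max()
            assert off < 1e-8 * np.diag(G).max()

    def test_unpenalized_first_direction_is_cross_covariance(self):
        y, X = signal_instance(3)
        fit = fit_pocre(y, X, 0.85, penalty="none", max_comp=1)
        v = X.T @ y
        cos = abs(fit.weights[:, 0] @ v) / np.linalg.norm(v)
        assert cos > 1 - 1e-10

    def test_beta_reproduces_component_predictions(self):
        for seed in range(5):
            y, X = signal_instance(seed)
            fit = fit_pocre(y, X, 0.85)
            lhs = X @ fit.beta
            rhs = fit.scores @ fit.q
            assert np.linalg.norm(lhs - rhs) <= 1e-10 * max(np.linalg.norm(rhs), 1.0)

    def test_beta_support_inside_loading_support(self):
        y, X = signal_instance(7)
        fit = fit_pocre(y, X, 0.85)
        loading_support = np.any(fit.weights != 0.0, axis=1)
        assert np.all(loading_support[fit.beta != 0.0])

    def test_duplicate_columns_get_identical_beta(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(100, 1))
        Z = rng.normal(size=(100, 18))
        X = np.column_stack([x, Z[:, :9], x, Z[:, 9:]])
        X -= X.mean(axis=0)
        y = 3.0 * X[:, 0] + 0.3 * rng.normal(size=100)
        y -= y.mean()
        fit = fit_pocre(y, X, 0.85)
        assert fit.beta[0] != 0.0
        assert fit.beta[0] == fit.beta[10]  # exact equality

    def test_pure_noise_mostly_yields_empty_model(self):
        empty = 0
        runs = 15
        for seed in range(runs):
            rng = np.random.default_rng(3000 + seed)
            X = rng.normal(size=(200, 500))
            X -= X.mean(axis=0)
            y = rng.normal(size=200)
            y -= y.mean()
            fit = fit_pocre(y, X, 0.9)
            empty += fit.n_components == 0
        assert empty > runs / 2

    def test_permuting_columns_permutes_beta(self):
        y, X = signal_instance(5)
        rng = np.random.default_rng(0)
        perm = rng.permutation(X.shape[1])
        f1 = fit_pocre(y, X, 0.85)
        f2 = fit_pocre(y, X[:, perm], 0.85)
        np.testing.assert_array_equal(f2.beta != 0.0, f1.beta[perm] != 0.0)
        np.testing.assert_allclose(f2.beta, f1.beta[perm], atol=1e-10)

    def test_sparsity_weakly_decreasing_in_lambda(self):
        sizes = []
        for lam in (0.80, 0.85, 0.90):
            support = 0
            for seed in range(8):
                y, X = signal_instance(seed, n=100, p=60, k=4, noise=1.0)
                support += int(np.sum(fit_pocre(y, X, lam).beta != 0.0))
            sizes.append(support)
        assert sizes[0] >= sizes[1] >= sizes[2]


class TestPocreLDAModel:
    def make_classes(self, seed, n=200, p=12, sep=4.0):
        rng = np.random.default_rng(seed)
        y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        X = rng.normal(size=(n, p))
        X[:, 0] += sep * y
        return y, X

    def test_requires_two_classes_and_valid_coding(self):
        X = np.zeros((10, 3))
        with pytest.raises(ValueError, match="classes"):
            PocreLDA(np.ones(10), X)
        with pytest.raises(ValueError, match="coded"):
            PocreLDA(np.arange(10), X)

    def test_zero_one_coding_accepted(self):
        y, X = self.make_classes(0)
        res01 = PocreLDA((y + 1) / 2, X).fit()
        respm = PocreLDA(y, X).fit()
        np.testing.assert_allclose(res01.params, respm.params)

    def test_separated_clouds_classified_perfectly(self):
        y, X = self.make_classes(1)
        res = PocreLDA(y, X).fit(lam=0.85)
        assert np.mean(res.classify(X) != y) == 0.0

    def test_zero_model_balanced_classes_all_control(self):
        rng = np.random.default_rng(2)
        y = np.array([1.0, -1.0] * 50)
        X = rng.normal(size=(100, 30))
        model = PocreLDA(y, X)
        res = model.fit(lam=0.9)
        if res.nonzero_mask.any():
            pytest.skip("seeded noise produced a nonempty model")
        assert res.intercept == 0.0
        assert np.all(res.classify(X) == -1.0)  # score 0 is not > 0

    def test_label_flip_negates_beta_and_classifications(self):
        y, X = self.make_classes(3, n=100)
        # force exact balance so the intercept is 0
        y[: len(y) // 2] = 1.0
        y[len(y) // 2 :] = -1.0
        r1 = PocreLDA(y, X).fit(0.85)
        r2 = PocreLDA(-y, X).fit(0.85)
        np.testing.assert_allclose(r2.params, -r1.params, atol=1e-10)
        np.testing.assert_array_equal(r2.classify(X), -r1.classify(X))

    def test_classify_is_deterministic(self):
        y, X = self.make_classes(4)
        res = PocreLDA(y, X).fit(0.85)
        np.testing.assert_array_equal(res.classify(X), res.classify(X))

    def test_column_count_mismatch_is_error(self):
        y, X = self.make_classes(5)
        res = PocreLDA(y, X).fit(0.85)
        with pytest.raises(ValueError, match="columns"):
            res.predict(X[:, :-1])

    def test_summary_mentions_key_fields(self):
        y, X = self.make_classes(6)
        res = PocreLDA(y, X, column_names=[f"snp{j}" for j in range(X.shape[1])]).fit()
        text = res.summary()
        assert "lambda" in text and "components" in text and "snp0" in text

    def test_model_dump_round_trips_beta(self, tmp_path):
        import pandas as pd

        y, X = self.make_classes(7)
        res = PocreLDA(y, X).fit(0.85)
        res.to_tsv(tmp_path / "m.tsv")
        back = pd.read_csv(tmp_path / "m.tsv", sep="\t", comment="#")
        np.testing.assert_allclose(back["beta"].to_numpy(), res.params, rtol=1e-10)


class TestSelectLambda:
    def test_default_grid_has_eleven_candidates(self):
        assert len(DEFAULT_LAMBDA_GRID) == 11
        assert DEFAULT_LAMBDA_GRID[0] == pytest.approx(0.80)
        assert DEFAULT_LAMBDA_GRID[-1] == pytest.approx(0.90)

    def test_single_candidate_grid(self):
        y, X = TestPocreLDAModel().make_classes(8)
        res = PocreLDA(y[:100], X[:100]).fit_select_lambda(
            y[100:], X[100:], grid=[0.85]
        )
        assert res.lambda_ == 0.85

    def test_ties_resolve_to_smallest_lambda(self):
        # perfectly separated data: every candidate has test error 0
        y, X = TestPocreLDAModel().make_classes(9, sep=8.0)
        res = PocreLDA(y[:100], X[:100]).fit_select_lambda(y[100:], X[100:])
        errs = [e for _, e, _, _ in res.lambda_path]
        assert min(errs) == errs[0] == 0.0
        assert res.lambda_ == pytest.approx(0.80)

    def test_empty_grid_rejected(self):
        y, X = TestPocreLDAModel().make_classes(10)
        with pytest.raises(ValueError, match="grid"):
            PocreLDA(y, X).fit_select_lambda(y, X, grid=[])
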