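import numpy as np
import pandas as pd
import pytest

from bmrepurpose import (
    compare_groups,
    drop_missing_drugs,
    knn_impute,
    ridge_fit,
    ridge_predict,
    sensitive_drugs,
)


def matrix(values, lines=None, drugs=None):
    values = np.asarray(values, dtype=float)
    lines = lines or [f"L{i}" for i in range(values.shape[0])]
    drugs = drugs or [f"D{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=lines, columns=drugs)


class TestDropMissing:
    def _with_missing(self, n_missing, n_lines=100):
        vals = np.full((n_lines, 2), 5.0)
        vals[:n_missing, 0] = np.nan
        return matrix(vals, drugs=["flagged", "clean"])

    def test_21_percent_missing_removed(self):
        out = drop_missing_drugs(self._with_missing(21), 0.20)
        assert list(out.columns) == ["clean"]

    def test_exactly_20_percent_kept(self):
        out = drop_missing_drugs(self._with_missing(20), 0.20)
        assert list(out.columns) == ["flagged", "clean"]

    def test_complete_matrix_unchanged(self):
        m = self._with_missing(0)
        pd.testing.assert_frame_equal(drop_missing_drugs(m, 0.20), m)


class TestKnnImpute:
    def test_complete_matrix_unchanged(self):
        m = matrix([[1.0, 2.0], [3.0, 4.0]])
        pd.testing.assert_frame_equal(knn_impute(m, k=1), m)

    def test_twin_row_fills_missing_entry(self):
        vals = [[1.0, 2.0, 3.0], [1.0, 2.0, np.nan], [9.0, 9.0, 9.0]]
        out = knn_impute(matrix(vals), k=1)
        assert out.iloc[1, 2] == pytest.approx(3.0)

    def test_no_observing_line_is_an_error(self):
        m = matrix([[1.0, np.nan], [2.0, np.nan]])
        with pytest.raises(ValueError, match="observes"):
            knn_impute(m, k=1)

    def test_imputed_values_within_observed_range(self, rng):
        vals = rng.uniform(1.0, 50.0, size=(20, 8))
        mask = rng.uniform(size=vals.shape) < 0.2
        mask[0] = False  # keep one full line
        vals[mask] = np.nan
        m = matrix(vals)
        out = knn_impute(m, k=3)
        assert not out.isna().any().any()
        for j, d in enumerate(m.columns):
            lo, hi = np.nanmin(vals[:, j]), np.nanmax(vals[:, j])
            assert (out[d] >= lo - 1e-12).all() and (out[d] <= hi + 1e-12).all()

    def test_beats_column_mean_on_rank_one_matrices(self):
        """Rank-1 structure: neighbors carry line effects column means miss."""
        wins = 0
        n_rep = 30
        for rep in range(n_rep):
            rng = np.random.default_rng(500 + rep)
            u = rng.uniform(0.5, 2.0, size=40)
            v = rng.uniform(1.0, 30.0, size=12)
            truth = np.outer(u, v)
            mask = rng.uniform(size=truth.shape) < 0.10
            obs = truth.copy()
            obs[mask] = np.nan
            if np.isnan(obs).all(axis=0).any() or mask.sum() == 0:
                continue
            m = matrix(obs)
            knn = knn_impute(m, k=5).to_numpy()
            col_mean = np.where(
                np.isnan(obs), np.nanmean(obs, axis=0, keepdims=True), obs
            )
            rmse_knn = np.sqrt(np.mean((knn[mask] - truth[mask]) ** 2))
            rmse_col = np.sqrt(np.mean((col_mean[mask] - truth[mask]) ** 2))
            wins += rmse_knn < rmse_col
        assert wins >= 0.95 * n_rep


class TestRidge:
    def _toy(self, rng, n=5, p=2):
        X = rng.normal(size=(p, n))
        beta = rng.normal(size=p)
        y = np.exp(X.T @ beta + 0.5)
        expr = pd.DataFrame(X, index=[f"g{i}" for i in range(p)],
                            columns=[f"L{i}" for i in range(n)])
        return expr, pd.Series(y, index=expr.columns), beta

    def test_lambda_zero_equals_ols(self, rng):
        expr, y, _ = self._toy(rng)
        model = ridge_fit(expr, y, lam=0.0)
        X = expr.to_numpy().T
        A = np.column_stack([np.ones(len(y)), X])
        ols = np.linalg.lstsq(A, np.log(y.to_numpy()), rcond=None)[0]
        assert model.intercept == pytest.approx(ols[0], abs=1e-8)
        np.testing.assert_allclose(model.coef.to_numpy(), ols[1:], atol=1e-8)

    def test_huge_lambda_predicts_training_mean(self, rng):
        expr, y, _ = self._toy(rng, n=10, p=3)
        model = ridge_fit(expr, y, lam=1e12)
        np.testing.assert_allclose(model.coef.to_numpy(), 0.0, atol=1e-9)
        pred = ridge_predict(model, expr)
        geo_mean = np.exp(np.mean(np.log(y)))
        np.testing.assert_allclose(pred, geo_mean, rtol=1e-6)

    def test_recovers_coefficients(self):
        rng = np.random.default_rng(42)
        n, p, sigma = 200, 10, 0.1
        X = rng.normal(size=(p, n))
        beta = rng.normal(size=p)
        y = np.exp(X.T @ beta + rng.normal(0, sigma, size=n))
        expr = pd.DataFrame(X, index=[f"g{i}" for i in range(p)],
                            columns=[f"L{i}" for i in range(n)])
        model = ridge_fit(expr, pd.Series(y, index=expr.columns))
        rel_err = np.linalg.norm(model.coef.to_numpy() - beta) / np.linalg.norm(beta)
        assert rel_err < 0.1

    def test_matches_sklearn_ridge_at_fixed_lambda(self, rng):
        from sklearn.linear_model import Ridge

        expr, y, _ = self._toy(rng, n=30, p=4)
        lam = 2.5
        model = ridge_fit(expr, y, lam=lam)
        sk = Ridge(alpha=lam, fit_intercept=True)
        sk.fit(expr.to_numpy().T, np.log(y.to_numpy()))
        np.testing.assert_allclose(model.coef.to_numpy(), sk.coef_, atol=1e-8)
        assert model.intercept == pytest.approx(sk.intercept_, abs=1e-8)

    def test_gene_reordering_invariance(self, rng):
        expr, y, _ = self._toy(rng, n=20, p=5)
        shuffled = expr.iloc[::-1]
        p1 = ridge_predict(ridge_fit(expr, y, lam=1.0), expr)
        p2 = ridge_predict(ridge_fit(shuffled, y, lam=1.0), shuffled)
        np.testing.assert_allclose(p1.to_numpy(), p2.to_numpy(), rtol=1e-9)

    def test_constant_response_gives_intercept_only(self, rng):
        expr, y, _ = self._toy(rng)
        y[:] = 3.0
        model = ridge_fit(expr, y)
        assert (model.coef == 0).all()
        np.testing.assert_allclose(ridge_predict(model, expr), 3.0)

    def test_negative_lambda_error(self, rng):
        expr, y, _ = self._toy(rng)
        with pytest.raises(ValueError):
            ridge_fit(expr, y, lam=-1.0)


class TestSensitiveDrugs:
    def _preds(self, values_by_screen):
        return {
            screen: pd.DataFrame({d: [v] * 3 for d, v in drugs.items()})
            for screen, drugs in values_by_screen.items()
        }

    def test_qualifying_in_both_screens_retained(self):
        preds = self._preds(
            {"gdsc1": {"navitoclax": 7.65}, "gdsc2": {"navitoclax": 7.65}}
        )
        assert sensitive_drugs(preds, 10.0) == {"navitoclax"}

    def test_exactly_threshold_excluded(self):
        preds = self._preds({"gdsc1": {"d": 10.0}, "gdsc2": {"d": 10.0}})
        assert sensitive_drugs(preds, 10.0) == set()

    def test_single_screen_qualification_excluded(self):
        preds = self._preds({"gdsc1": {"d": 5.0}, "gdsc2": {"d": 50.0}})
        assert sensitive_drugs(preds, 10.0) == set()

    def test_monotone_in_threshold(self):
        preds = self._preds(
            {"s1": {"a": 1.0, "b": 8.0, "c": 20.0}, "s2": {"a": 2.0, "b": 9.0, "c": 5.0}}
        )
        sizes = [len(sensitive_drugs(preds, t)) for t in (20.0, 10.0, 5.0, 1.5)]
        assert sizes == sorted(sizes, reverse=True)


class TestCompareGroups:
    def test_identical_groups_maximal_p(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        _, p = compare_groups(a, a)
        assert p > 0.99

    def test_separated_groups_match_exact_permutation(self):
        a = list(range(1, 11))
        b = [x + 100 for x in a]
        _, p = compare_groups(a, b)
        from math import comb

        exact = 2 / comb(20, 10)
        assert p == pytest.approx(exact, rel=1e-9)

    def test_power_at_two_sigma_shift(self):
        rejections = 0
        n_rep = 200
        for rep in range(n_rep):
            rng = np.random.default_rng(900 + rep)
            a = rng.normal(0.0, 1.0, 20)
            b = rng.normal(2.0, 1.0, 20)
            _, p = compare_groups(a, b)
            rejections += p < 0.05
        assert rejections / n_rep > 0.9

    def test_too_few_values_error(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])
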