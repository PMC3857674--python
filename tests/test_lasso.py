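import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from mixselect import LassoSelect, expand_predictors
from mixselect.design import standardize
from mixselect.shrinkage import (
    _poisson_alpha_grid,
    _poisson_lasso_path,
)


def soft_threshold(x, t):
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


@pytest.fixture
def orthonormal_design(rng):
    M = rng.normal(size=(64, 4))
    Q, _ = np.linalg.qr(M - M.mean(axis=0))
    return Q  # centered, orthonormal columns


class TestGaussian:
    def test_soft_threshold_oracle_on_orthonormal_design(self, orthonormal_design, rng):
        # with Z'Z = I the penalized solution is the soft-thresholded
        # projection: b_j = S((Z'y)_j, n*lambda)
        from sklearn.linear_model import lasso_path

        Q = orthonormal_design
        n = Q.shape[0]
        y = Q @ np.array([2.0, -1.0, 0.3, 0.0]) + 0.1 * rng.normal(size=n)
        yc = y - y.mean()
        z = Q.T @ yc
        alphas = np.geomspace(np.abs(z).max() / n, 1e-4, 30)
        al, coefs, _ = lasso_path(Q, yc, alphas=alphas)
        expected = np.sign(z)[:, None] * np.maximum(
            np.abs(z)[:, None] - n * al[None, :], 0.0
        )
        np.testing.assert_allclose(coefs, expected, atol=1e-6)

    def test_kkt_conditions_at_solution(self, s1_data):
        res = LassoSelect(s1_data.y, s1_data.predictors()).fit(seed=3)
        lam = res.info["chosen_lambda"]
        ps = standardize(s1_data.predictors())
        Z = ps.values()
        n = Z.shape[0]
        b_std = res.params.to_numpy() * ps.scale_sd  # back to standardized scale
        r = s1_data.y - s1_data.y.mean() - (Z - Z.mean(axis=0)) @ b_std
        grad = (Z - Z.mean(axis=0)).T @ r / n
        for g, b in zip(grad, b_std):
            if b == 0.0:
                assert abs(g) <= lam + 1e-6
            else:
                assert g == pytest.approx(lam * np.sign(b), abs=1e-6)

    def test_near_zero_penalty_recovers_ols(self, rng):
        X = rng.normal(size=(80, 3))
        ps = expand_predictors(pd.DataFrame(X, columns=["X1", "X2", "X3"]))
        y = X @ np.array([1.0, -2.0, 0.5]) + 0.5 * rng.normal(size=80)
        res = LassoSelect(y, ps).fit(seed=0, eps=1e-8)
        path = res.info["path"]
        A = np.column_stack([np.ones(80), ps.values()])
        ols = np.linalg.lstsq(A, y, rcond=None)[0][1:]
        np.testing.assert_allclose(path.coefs[:, -1], ols, atol=1e-4)

    def test_all_zero_above_lambda_max(self, s1_data):
        res = LassoSelect(s1_data.y, s1_data.predictors()).fit(seed=0)
        path = res.info["path"]
        assert np.all(path.coefs[:, 0] == 0.0)  # largest lambda kills everything

    def test_piecewise_linearity_between_knots(self, orthonormal_design):
        # orthonormal case: coefficients are exactly piecewise linear in lambda
        from sklearn.linear_model import lasso_path

        Q = orthonormal_design
        y = Q @ np.array([2.0, -1.0, 0.5, 0.0])
        n = len(y)
        z = Q.T @ y
        lams = np.array([0.02, 0.015, 0.01]) * np.abs(z).max() / n
        al, coefs, _ = lasso_path(Q, y, alphas=lams, tol=1e-14)
        order = np.argsort(al)[::-1]
        al, coefs = al[order], coefs[:, order]
        assert al[1] == pytest.approx((al[0] + al[2]) / 2)
        mid = (coefs[:, 0] + coefs[:, 2]) / 2
        np.testing.assert_allclose(coefs[:, 1], mid, atol=1e-8)

    def test_cp_rule_runs_and_differs_at_most_slightly(self, s1_data):
        res_cp = LassoSelect(s1_data.y, s1_data.predictors()).fit(seed=0, rule="cp")
        assert res_cp.info["path"].rule == "cp"
        assert res_cp.model_size <= s1_data.predictors().P

    def test_path_export(self, s1_data):
        res = LassoSelect(s1_data.y, s1_data.predictors()).fit(seed=0)
        df = res.info["path"].to_frame()
        assert {"lambda", "cv_error"} <= set(df.columns)
        assert len(df) == 100


class TestPoisson:
    def test_zero_penalty_matches_glm(self, s3_data):
        ps = standardize(s3_data.predictors())
        Z = ps.values()
        lo = np.log(s3_data.offset)
        B0, B = _poisson_lasso_path(Z, s3_data.y.astype(float), lo, np.array([1e-10]))
        glm = sm.GLM(
            s3_data.y, sm.add_constant(Z), family=sm.families.Poisson(), offset=lo
        ).fit()
        np.testing.assert_allclose(B[:, 0], glm.params[1:], atol=1e-6)
        assert B0[0] == pytest.approx(glm.params[0], abs=1e-6)

    def test_lambda_max_gives_null_model(self, s3_data):
        ps = standardize(s3_data.predictors())
        Z = ps.values()
        y = s3_data.y.astype(float)
        lo = np.log(s3_data.offset)
        alphas = _poisson_alpha_grid(Z, y, lo, 5, 1e-1)
        B0, B = _poisson_lasso_path(Z, y, lo, alphas[:1] * 1.0001)
        assert np.all(B[:, 0] == 0.0)
        # null fitted means are the offset scaled by exp(intercept)
        assert np.exp(B0[0]) * s3_data.offset.sum() == pytest.approx(y.sum(), rel=1e-6)

    def test_kkt_conditions_poisson(self, s3_data):
        ps = standardize(s3_data.predictors())
        Z = ps.values()
        y = s3_data.y.astype(float)
        lo = np.log(s3_data.offset)
        n = y.size
        alphas = _poisson_alpha_grid(Z, y, lo, 20, 1e-3)
        B0, B = _poisson_lasso_path(Z, y, lo, alphas)
        lam, b0, b = alphas[10], B0[10], B[:, 10]
        mu = np.exp(lo + b0 + Z @ b)
        grad = Z.T @ (mu - y) / n
        for g, bj in zip(grad, b):
            if bj == 0.0:
                assert abs(g) <= lam + 1e-6
            else:
                assert -g == pytest.approx(lam * np.sign(bj), abs=1e-6)

    def test_full_fit_selects_true_terms(self, s3_data):
        res = LassoSelect(
            s3_data.y, s3_data.predictors(), family="poisson", offset=s3_data.offset
        ).fit(seed=1)
        assert {"X1", "X3", "X1*X3"} <= set(res.selected)

    def test_count_validation(self, s3_data):
        ps = s3_data.predictors()
        with pytest.raises(ValueError, match="integer"):
            LassoSelect(s3_data.y + 0.5, ps, family="poisson", offset=s3_data.offset)
        with pytest.raises(ValueError, match="offset"):
            LassoSelect(s3_data.y, ps, family="poisson", offset=np.zeros(ps.n))
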