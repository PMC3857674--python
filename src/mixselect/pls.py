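"""Partial least-squares regression via the kernel algorithm.

For a univariate response the leading eigenvector of Z'yy'Z is proportional
to Z'y, so each step computes the weight vector w_a ∝ Z'y normalized so
||Z w_a|| = 1, the score f_a = Z w_a, the loading r_a = Z'f_a, and deflates
Z <- Z - f_a r_a'.  Coefficients for A components are reconstructed as

    beta_A = W_A (R_A' W_A)^{-1} q_A,   q_a = y'f_a,

which at A = rank(Z) equals the OLS solution.  The component count is the
first local minimum of 10-fold cross-validated PRESS (a local minimum must
improve on both neighbors by at least 1e-10 of the total PRESS; otherwise
the global minimum is used).

Every candidate predictor enters each component, so the model size is P by
construction.  Count outcomes are handled by iteratively reweighted PLS on
the Poisson working response with log offset (PLS-GLM).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .base import SelectionModel, SelectionResults, seeded_kfold

__all__ = ["KernelPLS", "PlsModel", "pls_fit"]

_LOCAL_MIN_TOL = 1e-10


@dataclass
class PlsModel:
    """Weights, scores metadata and the PRESS curve of a PLS fit."""

    weights: np.ndarray  # P x A (w_a)
    loadings: np.ndarray  # P x A (r_a)
    score_coef: np.ndarray  # q_a = y' f_a
    n_components: int
    press: np.ndarray  # CV PRESS (or deviance) for A = 1..max_components

    def press_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n_components": np.arange(1, self.press.size + 1), "press": self.press}
        )


def _pls_decompose(Zc: np.ndarray, yc: np.ndarray, A: int):
    """Kernel-PLS decomposition of centered data; returns (W, R, q)."""
    n, P = Zc.shape
    Zd = Zc.copy()
    W = np.zeros((P, A))
    R = np.zeros((P, A))
    q = np.zeros(A)
    a_eff = 0
    for a in range(A):
        w = Zd.T @ yc
        norm = np.linalg.norm(Zd @ w)
        if norm < 1e-12 or np.linalg.norm(w) < 1e-12:
            break
        w = w / norm  # ||Z w|| = 1
        f = Zd @ w
        r = Zd.T @ f  # f'f = 1 by construction
        W[:, a] = w
        R[:, a] = r
        q[a] = yc @ f
        Zd -= np.outer(f, r)
        a_eff += 1
    return W[:, :a_eff], R[:, :a_eff], q[:a_eff]


def _pls_coef(W, R, q, a: int) -> np.ndarray:
    """Coefficient vector using the leading ``a`` components."""
    Wa, Ra, qa = W[:, :a], R[:, :a], q[:a]
    return Wa @ np.linalg.solve(Ra.T @ Wa, qa)


def _first_local_min(press: np.ndarray) -> int:
    tol = _LOCAL_MIN_TOL * press.sum()
    m = press.size
    for a in range(m):
        left_ok = a == 0 or press[a] < press[a - 1] - tol
        right_ok = a == m - 1 or press[a] < press[a + 1] - tol
        if left_ok and right_ok:
            return a
    return int(np.argmin(press))


class KernelPLS(SelectionModel):
    """Kernel-algorithm PLS with PRESS-selected component count."""

    method_name = "plsr"

    def fit(self, max_components: int | None = None, folds: int = 10,
            seed=None, n_components: int | None = None) -> SelectionResults:
        P = self.predictors.P
        if max_components is None:
            max_components = min(P, self.nobs - 2, 10)
        max_components = min(max_components, P, self.nobs - 2)
        if max_components < 1:
            raise ValueError("need at least one component")
        if self.family == "gaussian":
            return self._fit_gaussian(max_components, folds, seed, n_components)
        return self._fit_poisson(max_components, folds, seed, n_components)

    def _fit_gaussian(self, max_components, folds, seed, n_components):
        Z = self.predictors.values()
        y = self.endog
        if n_components is None:
            kf = seeded_kfold(folds, seed)
            press = np.zeros(max_components)
            for tr, te in kf.split(Z):
                zbar, ybar = Z[tr].mean(axis=0), y[tr].mean()
                W, R, q = _pls_decompose(Z[tr] - zbar, y[tr] - ybar, max_components)
                for a in range(1, max_components + 1):
                    a_use = min(a, W.shape[1])
                    if a_use == 0:
                        pred = np.full(te.size, ybar)
                    else:
                        b = _pls_coef(W, R, q, a_use)
                        pred = ybar + (Z[te] - zbar) @ b
                    press[a - 1] += float(np.sum((y[te] - pred) ** 2))
            A = _first_local_min(press) + 1
        else:
            press = np.full(max_components, np.nan)
            A = int(n_components)

        zbar, ybar = Z.mean(axis=0), y.mean()
        W, R, q = _pls_decompose(Z - zbar, y - ybar, max_components)
        A = min(A, W.shape[1])
        b = _pls_coef(W, R, q, A)
        if self.predictors.is_standardized:
            b0, b = self.predictors.destandardize_coef(ybar - zbar @ b, b)
        else:
            b0 = ybar - zbar @ b
        res = self._results(
            intercept=b0, coef=b, selected=self.predictors.names,
            model_size=self.predictors.P, n_components=A,
        )
        res.info["pls"] = PlsModel(W, R, q, A, press)
        return res

    def _fit_poisson(self, max_components, folds, seed, n_components):
        Z = self.predictors.values()
        y = self.endog
        log_off = np.log(self.offset)
        if n_components is None:
            kf = seeded_kfold(folds, seed)
            press = np.zeros(max_components)
            for tr, te in kf.split(Z):
                for a in range(1, max_components + 1):
                    b0, b = _irls_pls(Z[tr], y[tr], log_off[tr], a)
                    mu = np.exp(np.clip(log_off[te] + b0 + Z[te] @ b, -30, 30))
                    press[a - 1] += float(np.sum(_dev_terms(y[te], mu)))
            A = _first_local_min(press) + 1
        else:
            press = np.full(max_components, np.nan)
            A = int(n_components)

        b0, b = _irls_pls(Z, y, log_off, A)
        if self.predictors.is_standardized:
            b0, b = self.predictors.destandardize_coef(b0, b)
        res = self._results(
            intercept=b0, coef=b, selected=self.predictors.names,
            model_size=self.predictors.P, n_components=A,
        )
        res.info["pls"] = PlsModel(
            np.zeros((self.predictors.P, 0)), np.zeros((self.predictors.P, 0)),
            np.zeros(0), A, press,
        )
        return res


def _dev_terms(y, mu):
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
    return 2.0 * (term - (y - mu))


def _irls_pls(Z, y, log_off, A, max_iter: int = 15, tol: float = 1e-7):
    """PLS fit inside an IRLS loop on the Poisson working response."""
    n, P = Z.shape
    b0 = float(np.log(max(y.sum(), 0.5) / np.exp(log_off).sum()))
    b = np.zeros(P)
    for _ in range(max_iter):
        eta_lin = b0 + Z @ b
        eta = np.clip(log_off + eta_lin, -30, 30)
        mu = np.exp(eta)
        w = mu
        z = eta_lin + (y - mu) / np.maximum(mu, 1e-10)
        sw = np.sqrt(w)
        wbar_z = (w @ Z) / w.sum()
        wbar_y = (w @ z) / w.sum()
        Zc = sw[:, None] * (Z - wbar_z)
        yc = sw * (z - wbar_y)
        W, R, q = _pls_decompose(Zc, yc, A)
        a_use = min(A, W.shape[1])
        if a_use == 0:
            new_b = np.zeros(P)
        else:
            new_b = _pls_coef(W, R, q, a_use)
        new_b0 = wbar_y - wbar_z @ new_b
        if np.max(np.abs(new_b - b)) + abs(new_b0 - b0) < tol:
            b0, b = float(new_b0), new_b
            break
        b0, b = float(new_b0), new_b
    return b0, b


def pls_fit(ps, y, family: str = "gaussian", offset=None,
            max_components: int | None = None, folds: int = 10,
            seed=None) -> SelectionResults:
    return KernelPLS(y, ps, family=family, offset=offset).fit(
        max_components=max_components, folds=folds, seed=seed
    )
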