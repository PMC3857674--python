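"""Supervised principal component analysis.

Steps: (1) compute a univariate Wald statistic for every candidate column
(OLS t for continuous outcomes; Poisson GLM Wald z, with log offset, for
counts); (2) retain the columns whose |Wald| exceeds a threshold zeta, with
zeta chosen by minimizing 10-fold cross-validated prediction error (squared
error, or Poisson deviance) of the q-component refit over a grid of
midpoints between the sorted |Wald| values; (3) take the first q principal
components of the column-standardized reduced matrix Z'; (4) regress the
outcome on those components and back-map per-predictor effects through the
loadings:

    beta_s = sum_i b_i alpha_is   (0 for screened-out columns).

The reported model size is the number of retained columns S, not q.
Loading signs are fixed so each loading vector's largest-magnitude entry is
positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .base import SelectionModel, SelectionResults, seeded_kfold

__all__ = ["SupervisedPCA", "SpcaModel", "spca_fit"]


@dataclass
class SpcaModel:
    """Screening and component details of a supervised-PCA fit."""

    wald: pd.Series
    zeta: float
    retained: list
    q: int
    loadings: np.ndarray  # S x q, orthonormal columns
    component_coef: np.ndarray  # b_1..b_q
    backmapped_std: pd.Series  # coefficients on the standardized Z' scale
    cv_grid: pd.DataFrame  # zeta candidates and their CV error

    def loadings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.loadings, index=self.retained,
            columns=[f"PC{i + 1}" for i in range(self.q)],
        )


class SupervisedPCA(SelectionModel):
    """Wald screening + PCA + component regression, Gaussian or Poisson."""

    method_name = "spca"

    def fit(self, q: int = 1, folds: int = 10, seed=None) -> SelectionResults:
        if self.nobs <= folds:
            raise ValueError("need n > folds for cross-validation")
        Z = self.predictors.values()
        y = self.endog
        names = self.predictors.names
        P = Z.shape[1]

        wald = _univariate_wald(Z, y, self.family, self.offset)
        absw = np.abs(wald)
        order = np.sort(np.unique(absw))
        # candidate thresholds: one below the minimum (retain everything)
        # plus midpoints between consecutive sorted |Wald| values
        cands = [order[0] - 1.0] + [
            0.5 * (order[i] + order[i + 1]) for i in range(order.size - 1)
        ]
        cands = [z for z in cands if np.sum(absw > z) > q]  # need S > q
        if not cands:
            cands = [order[0] - 1.0] if np.sum(absw > order[0] - 1.0) > 0 else []
        if not cands:
            return self._empty_fit(wald, names)

        kf = list(seeded_kfold(folds, seed).split(Z))
        errs = np.zeros(len(cands))
        for z_i, zeta in enumerate(cands):
            cols = np.flatnonzero(absw > zeta)
            qq = min(q, cols.size)
            fold_err = []
            for tr, te in kf:
                fold_err.append(
                    _cv_component_error(
                        Z, y, self.offset, cols, qq, tr, te, self.family
                    )
                )
            errs[z_i] = float(np.mean(fold_err))
        # minimum CV error; ties go to the largest zeta (smallest model)
        best = max(
            range(len(cands)),
            key=lambda i: (-(errs[i]), cands[i]),
        )
        zeta = float(cands[best])
        cols = np.flatnonzero(absw > zeta)
        qq = min(q, cols.size)

        mean, sd, V, b, icpt = _component_fit(
            Z, y, self.offset, cols, qq, self.family
        )
        beta_std = V @ b  # on the standardized Z' scale
        coef = np.zeros(P)
        coef[cols] = beta_std / sd  # original Z scale
        intercept = icpt - float((beta_std / sd) @ mean)

        spca = SpcaModel(
            wald=pd.Series(wald, index=names),
            zeta=zeta,
            retained=[names[c] for c in cols],
            q=qq,
            loadings=V,
            component_coef=b,
            backmapped_std=pd.Series(beta_std, index=[names[c] for c in cols]),
            cv_grid=pd.DataFrame({"zeta": cands, "cv_error": errs}),
        )
        res = self._results(
            intercept=intercept,
            coef=coef,
            selected=spca.retained,
            model_size=len(cols),
            zeta=zeta,
            q=qq,
        )
        res.info["spca"] = spca
        return res

    def _empty_fit(self, wald, names):
        import warnings

        warnings.warn("all columns screened out; returning the empty model")
        res = self._results(
            intercept=float(self.endog.mean()), coef=np.zeros(len(names)),
            selected=[], model_size=0,
        )
        res.info["spca"] = SpcaModel(
            wald=pd.Series(wald, index=names), zeta=np.inf, retained=[],
            q=0, loadings=np.zeros((0, 0)), component_coef=np.zeros(0),
            backmapped_std=pd.Series(dtype=float),
            cv_grid=pd.DataFrame(columns=["zeta", "cv_error"]),
        )
        return res


def _univariate_wald(Z, y, family, offset) -> np.ndarray:
    n, P = Z.shape
    out = np.empty(P)
    if family == "gaussian":
        yc = y - y.mean()
        for j in range(P):
            x = Z[:, j]
            xc = x - x.mean()
            sxx = xc @ xc
            if sxx <= 0:
                out[j] = 0.0
                continue
            b = (xc @ yc) / sxx
            resid = yc - b * xc
            s2 = (resid @ resid) / max(n - 2, 1)
            out[j] = b / np.sqrt(s2 / sxx) if s2 > 0 else np.inf * np.sign(b)
    else:
        log_off = np.log(offset)
        for j in range(P):
            X = sm.add_constant(Z[:, [j]], has_constant="add")
            try:
                fit = sm.GLM(y, X, family=sm.families.Poisson(), offset=log_off).fit()
                out[j] = fit.tvalues[1]
            except Exception:
                out[j] = 0.0
    return out


def _pca_loadings(Zs: np.ndarray, q: int) -> np.ndarray:
    """Orthonormal loadings of the first q PCs of a column-standardized
    matrix, signs fixed so each vector's largest |entry| is positive."""
    _, _, Vt = np.linalg.svd(Zs, full_matrices=False)
    V = Vt[:q].T
    for i in range(V.shape[1]):
        k = int(np.argmax(np.abs(V[:, i])))
        if V[k, i] < 0:
            V[:, i] = -V[:, i]
    return V


def _component_fit(Z, y, offset, cols, q, family):
    """Standardize the retained columns, extract q PCs, and regress the
    outcome on the component scores.  Returns (mean, sd, loadings, b, icpt)."""
    Zr = Z[:, cols]
    mean = Zr.mean(axis=0)
    sd = Zr.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    Zs = (Zr - mean) / sd
    V = _pca_loadings(Zs, q)
    Q = Zs @ V
    X = sm.add_constant(Q, has_constant="add")
    if family == "gaussian":
        fit = sm.OLS(y, X).fit()
    else:
        fit = sm.GLM(y, X, family=sm.families.Poisson(), offset=np.log(offset)).fit()
    return mean, sd, V, np.asarray(fit.params[1:]), float(fit.params[0])


def _cv_component_error(Z, y, offset, cols, q, tr, te, family) -> float:
    Zr = Z[:, cols]
    mean = Zr[tr].mean(axis=0)
    sd = Zr[tr].std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    Zs_tr = (Zr[tr] - mean) / sd
    Zs_te = (Zr[te] - mean) / sd
    V = _pca_loadings(Zs_tr, q)
    Q_tr = Zs_tr @ V
    Q_te = Zs_te @ V
    X_tr = sm.add_constant(Q_tr, has_constant="add")
    X_te = sm.add_constant(Q_te, has_constant="add")
    if family == "gaussian":
        fit = sm.OLS(y[tr], X_tr).fit()
        pred = X_te @ fit.params
        return float(np.mean((y[te] - pred) ** 2))
    log_off = np.log(offset)
    fit = sm.GLM(
        y[tr], X_tr, family=sm.families.Poisson(), offset=log_off[tr]
    ).fit()
    mu = np.exp(np.clip(log_off[te] + X_te @ fit.params, -30, 30))
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y[te] > 0, y[te] * np.log(np.where(y[te] > 0, y[te], 1.0) / mu), 0.0)
    return float(np.mean(2.0 * (term - (y[te] - mu))))


def spca_fit(ps, y, family: str = "gaussian", offset=None, q: int = 1,
             folds: int = 10, seed=None) -> SelectionResults:
    return SupervisedPCA(y, ps, family=family, offset=offset).fit(q=q, folds=folds, seed=seed)
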