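"""Bayesian model averaging over subsets of the candidate predictors.

All 2^P subset models (up to an enumeration cap) are enumerated under a
uniform model prior; each model's marginal likelihood is approximated by
exp(-BIC/2), so posterior model probabilities are

    P(M_d | Y, Z) = exp(-BIC_d / 2) / sum_i exp(-BIC_i / 2).

Per-coefficient posterior means and variances follow from the laws of total
expectation and total variance over the model space (a coefficient is
exactly 0 under models that exclude it).  A predictor is "identified" when
its posterior inclusion probability (PIP) exceeds a threshold (default
0.10).  Reported point estimates are the unconditional model-averaged
means, zeros included.

Above the enumeration cap the model refuses and points at the two-step
CART-screening strategy, which supplies a reduced candidate set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .base import SelectionModel, SelectionResults

__all__ = ["BmaSelect", "BmaResult", "bma_fit"]


@dataclass
class BmaResult:
    """Enumerated model space with posterior weights and moments."""

    models: list  # list of tuples of column indices
    weights: np.ndarray
    pip: pd.Series
    post_mean: pd.Series
    post_var: pd.Series
    threshold: float

    def top_models(self, k: int = 10) -> pd.DataFrame:
        order = np.argsort(self.weights)[::-1][:k]
        names = self.pip.index
        rows = [
            {
                "model": " + ".join(names[i] for i in self.models[d]) or "(intercept)",
                "size": len(self.models[d]),
                "posterior_prob": self.weights[d],
            }
            for d in order
        ]
        return pd.DataFrame(rows)


class BmaSelect(SelectionModel):
    """BIC-approximated Bayesian model averaging (Gaussian or Poisson)."""

    method_name = "bma"

    def fit(self, enumeration_cap: int = 25, pip_threshold: float = 0.10,
            occam_window: float | None = None) -> SelectionResults:
        P = self.predictors.P
        if P > enumeration_cap:
            raise ValueError(
                f"P={P} exceeds the enumeration cap ({enumeration_cap}); "
                "apply a preliminary screen first (e.g. the two-step CART "
                "strategy) to reduce the candidate set"
            )
        Z = self.predictors.values()
        y = self.endog
        n = y.size

        models: list[tuple] = []
        bics = []
        icpts = []
        est = []  # per-model dense coefficient vectors
        var = []  # per-model dense coefficient variances
        if self.family == "gaussian":
            gram_A = np.column_stack([np.ones(n), Z])
            G = gram_A.T @ gram_A
            g = gram_A.T @ y
            yty = float(y @ y)
        for subset in _all_subsets(P):
            k = len(subset)
            if n <= k + 1:
                continue
            if self.family == "gaussian":
                idx = np.concatenate(([0], np.asarray(subset, dtype=int) + 1))
                Gs = G[np.ix_(idx, idx)]
                gs = g[idx]
                try:
                    cho = np.linalg.cholesky(Gs)
                except np.linalg.LinAlgError:
                    continue
                b = _cho_solve(cho, gs)
                rss = max(yty - float(b @ gs), 1e-300)
                bic = n * np.log(rss / n) + (k + 1) * np.log(n)
                sigma2 = rss / (n - k - 1)
                inv_diag = _cho_inv_diag(cho)
                icpt = b[0]
                bvec = np.zeros(P)
                vvec = np.zeros(P)
                bvec[list(subset)] = b[1:]
                vvec[list(subset)] = sigma2 * inv_diag[1:]
            else:
                cols = list(subset)
                X = sm.add_constant(Z[:, cols], has_constant="add")
                glm = sm.GLM(
                    y, X, family=sm.families.Poisson(),
                    offset=np.log(self.offset),
                )
                try:
                    fit = glm.fit()
                except Exception:
                    continue
                bic = -2.0 * fit.llf + (k + 1) * np.log(n)
                icpt = fit.params[0]
                bvec = np.zeros(P)
                vvec = np.zeros(P)
                bvec[cols] = fit.params[1:]
                vvec[cols] = np.diag(fit.cov_params())[1:]
            models.append(subset)
            bics.append(bic)
            icpts.append(icpt)
            est.append(bvec)
            var.append(vvec)

        bics = np.asarray(bics)
        icpts = np.asarray(icpts)
        est = np.asarray(est)
        var = np.asarray(var)
        w = np.exp(-(bics - bics.min()) / 2.0)
        w /= w.sum()
        if occam_window is not None:
            keep = w >= w.max() * occam_window
            models = [m for m, k_ in zip(models, keep) if k_]
            w, icpts, est, var = w[keep], icpts[keep], est[keep], var[keep]
            w = w / w.sum()

        post_mean = w @ est
        post_var = w @ (var + est**2) - post_mean**2
        incl = np.zeros(P)
        for m, wt in zip(models, w):
            incl[list(m)] += wt
        names = self.predictors.names
        bma = BmaResult(
            models=models,
            weights=w,
            pip=pd.Series(incl, index=names),
            post_mean=pd.Series(post_mean, index=names),
            post_var=pd.Series(np.maximum(post_var, 0.0), index=names),
            threshold=pip_threshold,
        )
        selected = [nm for nm, p in bma.pip.items() if p > pip_threshold]
        res = self._results(
            intercept=float(w @ icpts),
            coef=post_mean,
            selected=selected,
            pip_threshold=pip_threshold,
        )
        res.info["bma"] = bma
        return res


def _all_subsets(P: int):
    for k in range(P + 1):
        yield from itertools.combinations(range(P), k)


def _cho_solve(cho: np.ndarray, g: np.ndarray) -> np.ndarray:
    from scipy.linalg import cho_solve

    return cho_solve((cho, True), g)


def _cho_inv_diag(cho: np.ndarray) -> np.ndarray:
    from scipy.linalg import cho_solve

    inv = cho_solve((cho, True), np.eye(cho.shape[0]))
    return np.diag(inv)


def bma_fit(ps, y, family: str = "gaussian", offset=None, **kw) -> SelectionResults:
    return BmaSelect(y, ps, family=family, offset=offset).fit(**kw)
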