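"""Regression-tree screening of raw exposures.

A preliminary tree is grown by exhaustive best-split search (least-squares
impurity), then pruned by cost-complexity with the subtree chosen to
minimize 10-fold cross-validated prediction error (a 1-SE rule is
available).  The exposures appearing in at least one split of the pruned
tree form the screened set used as step 1 of the two-step modelling
strategy.

Only continuous responses are supported; the two-step strategy is therefore
restricted to the cross-sectional (Gaussian) setting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .base import SelectionModel, SelectionResults, seeded_kfold

__all__ = ["RegressionTreeScreen", "TreeModel", "fit_tree", "screen_variables"]


@dataclass
class TreeModel:
    """Fitted (pruned) regression tree plus its pruning sequence.

    ``estimator`` is the pruned sklearn tree; ``pruning_alphas`` /
    ``pruning_cv_error`` record the cost-complexity sequence and its
    cross-validated error; ``alpha`` is the chosen complexity penalty.
    """

    estimator: DecisionTreeRegressor
    feature_names: list
    pruning_alphas: np.ndarray
    pruning_cv_error: np.ndarray
    pruning_cv_se: np.ndarray
    alpha: float
    cv_rule: str
    min_node_size: int

    @property
    def n_leaves(self) -> int:
        return self.estimator.get_n_leaves()

    def split_variables(self) -> set:
        t = self.estimator.tree_
        used = {int(f) for f in t.feature if f >= 0}
        return {self.feature_names[i] for i in used}

    def predict(self, X) -> np.ndarray:
        return self.estimator.predict(np.asarray(X, dtype=float))

    def _node_dict(self, node: int) -> dict:
        t = self.estimator.tree_
        d = {
            "n": int(t.n_node_samples[node]),
            "mean": float(t.value[node].ravel()[0]),
            "sse": float(t.impurity[node] * t.n_node_samples[node]),
        }
        if t.children_left[node] >= 0:
            d["split_var"] = self.feature_names[int(t.feature[node])]
            d["split_point"] = float(t.threshold[node])
            d["left"] = self._node_dict(int(t.children_left[node]))
            d["right"] = self._node_dict(int(t.children_right[node]))
        return d

    def to_json(self) -> str:
        return json.dumps(self._node_dict(0), indent=1)

    def format(self) -> str:
        """Indented text rendering of the pruned tree."""
        lines: list[str] = []

        def rec(d: dict, indent: int, label: str) -> None:
            head = f"{' ' * indent}{label}n={d['n']} mean={d['mean']:.3f}"
            if "split_var" in d:
                head += f" | split {d['split_var']} <= {d['split_point']:.4g}"
            lines.append(head)
            if "split_var" in d:
                rec(d["left"], indent + 2, "L: ")
                rec(d["right"], indent + 2, "R: ")

        rec(self._node_dict(0), 0, "")
        return "\n".join(lines)


class RegressionTreeScreen(SelectionModel):
    """CART-style screening model on the raw exposures.

    ``predictors`` may be a PredictorSet (its main-effect columns are used)
    or the screen can be built directly with :func:`fit_tree`.
    """

    supported_families = ("gaussian",)
    method_name = "cart"

    def __init__(self, endog, predictors, family: str = "gaussian", offset=None):
        super().__init__(endog, predictors, family, offset)
        mains = self.predictors.exposure_names
        self._X = self.predictors.Z[mains]

    def fit(self, min_node_size: int = 20, cv_folds: int = 10,
            cv_rule: str = "min", seed=None) -> SelectionResults:
        tree = fit_tree(
            self._X, self.endog, min_node_size=min_node_size,
            cv_folds=cv_folds, cv_rule=cv_rule, seed=seed,
        )
        screened = screen_variables(tree)
        coef = np.zeros(self.predictors.P)
        res = self._results(
            intercept=float(self.endog.mean()),
            coef=coef,
            selected=[c for c in self.predictors.names if c in screened],
            n_leaves=tree.n_leaves,
            alpha=tree.alpha,
        )
        res.info["tree"] = tree
        return res


def fit_tree(X, y, min_node_size: int = 20, cv_folds: int = 10,
             cv_rule: str = "min", seed=None) -> TreeModel:
    """Grow a least-squares regression tree and prune it by 10-fold CV.

    ``min_node_size`` is the smallest node eligible for splitting; leaves
    may be as small as max(1, min_node_size // 3).  The preliminary tree is
    grown with zero complexity penalty; candidate subtrees come from the
    cost-complexity pruning sequence, and the chosen penalty minimizes the
    cross-validated squared error (``cv_rule="min"``) or is the largest
    penalty within one standard error of that minimum (``"1-se"``).
    A constant response yields a root-only tree.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        feature_names = [f"X{i + 1}" for i in range(Xv.shape[1])]
    y = np.asarray(y, dtype=float)
    n = y.size
    if n <= 2 * min_node_size // 3:
        raise ValueError("sample too small for the requested min_node_size")
    if cv_rule not in ("min", "1-se"):
        raise ValueError("cv_rule must be 'min' or '1-se'")
    leaf = max(1, min_node_size // 3)

    def grow() -> DecisionTreeRegressor:
        return DecisionTreeRegressor(
            criterion="squared_error",
            min_samples_split=min_node_size,
            min_samples_leaf=leaf,
            random_state=0,  # exhaustive search; state only breaks exact ties
        )

    full = grow().fit(Xv, y)
    path = full.cost_complexity_pruning_path(Xv, y)
    alphas = np.asarray(path.ccp_alphas)
    # evaluate at geometric midpoints of consecutive alphas (standard trick:
    # any alpha strictly between two knots selects the same subtree)
    if alphas.size > 1:
        inner = np.sqrt(np.clip(alphas[:-1], 0, None) * alphas[1:])
        inner[alphas[:-1] == 0] = alphas[1:][alphas[:-1] == 0] / 2.0
        cand = np.concatenate(([0.0], inner))
    else:
        cand = np.array([0.0])

    kf = seeded_kfold(cv_folds, seed)
    fold_err = np.zeros((cv_folds, cand.size))
    for f, (tr, te) in enumerate(kf.split(Xv)):
        for a_i, a in enumerate(cand):
            est = grow().set_params(ccp_alpha=a).fit(Xv[tr], y[tr])
            pred = est.predict(Xv[te])
            fold_err[f, a_i] = np.mean((y[te] - pred) ** 2)
    cv_err = fold_err.mean(axis=0)
    cv_se = fold_err.std(axis=0, ddof=1) / np.sqrt(cv_folds)

    i_min = int(np.argmin(cv_err))
    if cv_rule == "1-se":
        limit = cv_err[i_min] + cv_se[i_min]
        ok = np.flatnonzero(cv_err <= limit)
        chosen = int(ok.max())  # largest alpha within 1 SE => smallest tree
    else:
        chosen = i_min
    alpha = float(cand[chosen])
    pruned = grow().set_params(ccp_alpha=alpha).fit(Xv, y)
    return TreeModel(
        estimator=pruned,
        feature_names=feature_names,
        pruning_alphas=cand,
        pruning_cv_error=cv_err,
        pruning_cv_se=cv_se,
        alpha=alpha,
        cv_rule=cv_rule,
        min_node_size=min_node_size,
    )


def screen_variables(tree: TreeModel) -> set:
    """Exposures appearing in >= 1 split of the pruned tree (may be empty)."""
    return tree.split_variables()
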