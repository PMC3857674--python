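"""Deletion/Substitution/Addition model search.

Starting from the intercept-only model, the search repeatedly evaluates

* the *deletion* set (all models of size p-1 obtained by dropping a term),
* the *substitution* set (size p, one term swapped for a new one), and
* the *addition* set (size p+1, one new term appended),

updating a per-size record of the best residual sum of squares found.  A
move is taken whenever it strictly improves the stored per-size minimum
(moves tried in the name order: deletion, substitution, addition; ties in
the objective broken by lowest column index).  The search terminates when
no move improves any per-size minimum and addition would exceed the size
cap.  The final model size is chosen by minimum cross-validated squared
error risk over the per-size best models; an OLS refit on the selected
terms gives the reported coefficients.

The candidate basis is the PredictorSet columns (main effects and pairwise
products only): interaction order and sum of powers are both capped at 2 by
construction.  Continuous outcomes only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .base import SelectionModel, SelectionResults, seeded_kfold

__all__ = ["DsaSelect", "DsaConfig", "dsa_search"]


@dataclass(frozen=True)
class DsaConfig:
    max_size: int | None = None  # default min(P, 10)
    max_order: int = 2
    max_sum_powers: int = 2
    cv_folds: int = 5
    seed: int | None = None


class _Gram:
    """Cached cross-products for fast subset OLS (intercept included)."""

    def __init__(self, Z: np.ndarray, y: np.ndarray):
        n = y.size
        A = np.column_stack([np.ones(n), Z])
        self.G = A.T @ A
        self.g = A.T @ y
        self.yty = float(y @ y)
        self.n = n

    def rss(self, terms: tuple) -> float:
        idx = np.concatenate(([0], np.asarray(terms, dtype=int) + 1))
        G = self.G[np.ix_(idx, idx)]
        g = self.g[idx]
        try:
            b = np.linalg.solve(G, g)
        except np.linalg.LinAlgError:
            b = np.linalg.lstsq(G, g, rcond=None)[0]
        return max(self.yty - float(b @ g), 0.0)

    def coef(self, terms: tuple) -> np.ndarray:
        idx = np.concatenate(([0], np.asarray(terms, dtype=int) + 1))
        G = self.G[np.ix_(idx, idx)]
        g = self.g[idx]
        try:
            return np.linalg.solve(G, g)
        except np.linalg.LinAlgError:
            return np.linalg.lstsq(G, g, rcond=None)[0]


@dataclass
class DsaState:
    """Per-size best models found so far and the search trajectory."""

    best: dict = field(default_factory=dict)  # size -> (terms tuple, rss)
    current: tuple = ()
    move_log: list = field(default_factory=list)

    def record(self, terms: tuple, rss: float) -> bool:
        """Store if strictly better than the saved minimum at this size."""
        size = len(terms)
        old = self.best.get(size)
        if old is None or rss < old[1] - 1e-12:
            self.best[size] = (terms, rss)
            return True
        return False


def _search(gram: _Gram, P: int, max_size: int) -> DsaState:
    state = DsaState()
    state.best[0] = ((), gram.rss(()))
    state.current = ()
    while True:
        cur = state.current
        p = len(cur)
        moved = False
        # deletion
        if p > 0:
            cands = [tuple(t for t in cur if t != drop) for drop in cur]
            moved = _try_move(state, gram, cands, "del")
            if moved:
                continue
        # substitution
        if p > 0:
            in_set = set(cur)
            cands = []
            for i, drop in enumerate(cur):
                for add in range(P):
                    if add in in_set:
                        continue
                    cands.append(tuple(sorted(cur[:i] + cur[i + 1:] + (add,))))
            moved = _try_move(state, gram, cands, "sub")
            if moved:
                continue
        # addition
        if p < max_size:
            in_set = set(cur)
            cands = [tuple(sorted(cur + (add,))) for add in range(P) if add not in in_set]
            moved = _try_move(state, gram, cands, "add")
            if moved:
                continue
        break
    return state


def _try_move(state: DsaState, gram: _Gram, cands: list, kind: str) -> bool:
    """Evaluate a move set; if its best member improves the stored per-size
    minimum, move there.  Candidates are scanned in construction order, so
    objective ties resolve to the lowest column indices."""
    best_terms, best_rss = None, np.inf
    for t in cands:
        r = gram.rss(t)
        if r < best_rss - 1e-12:
            best_terms, best_rss = t, r
    if best_terms is None:
        return False
    if state.record(best_terms, best_rss):
        state.current = best_terms
        state.move_log.append((kind, best_terms, best_rss))
        return True
    return False


class DsaSelect(SelectionModel):
    """Deletion/Substitution/Addition search with CV size selection."""

    supported_families = ("gaussian",)
    method_name = "dsa"

    def fit(self, max_size: int | None = None, cv_folds: int = 5,
            seed=None, config: DsaConfig | None = None) -> SelectionResults:
        if config is not None:
            max_size, cv_folds, seed = config.max_size, config.cv_folds, config.seed
        P = self.predictors.P
        if max_size is None:
            max_size = min(P, 10)
        if not 0 <= max_size <= P:
            raise ValueError("max_size must lie in [0, P]")
        Z = self.predictors.values()
        y = self.endog
        n = y.size

        # full-data search
        state = _search(_Gram(Z, y), P, max_size)

        # cross-validated risk per model size
        if max_size > 0:
            kf = seeded_kfold(cv_folds, seed)
            risks = np.full((cv_folds, max_size + 1), np.nan)
            for f, (tr, te) in enumerate(kf.split(Z)):
                gram_tr = _Gram(Z[tr], y[tr])
                st = _search(gram_tr, P, max_size)
                for size, (terms, _) in st.best.items():
                    b = gram_tr.coef(terms)
                    A_te = np.column_stack(
                        [np.ones(te.size), Z[np.ix_(te, np.asarray(terms, dtype=int))]]
                    ) if terms else np.ones((te.size, 1))
                    pred = A_te @ b
                    risks[f, size] = np.mean((y[te] - pred) ** 2)
            mean_risk = np.full(max_size + 1, np.nan)
            for s in range(max_size + 1):
                v = risks[:, s]
                v = v[~np.isnan(v)]
                if v.size:
                    mean_risk[s] = v.mean()
            sizes_ok = np.flatnonzero(~np.isnan(mean_risk))
            best_size = int(sizes_ok[np.argmin(mean_risk[sizes_ok])])
        else:
            mean_risk = np.array([np.nan])
            best_size = 0

        terms, rss = state.best.get(best_size, ((), state.best[0][1]))
        if n <= len(terms):
            raise ValueError("selected model size exceeds sample size")
        gram = _Gram(Z, y)
        b = gram.coef(terms)
        coef = np.zeros(P)
        coef[list(terms)] = b[1:]
        names = self.predictors.names
        if self.predictors.is_standardized:
            b0, coef = self.predictors.destandardize_coef(b[0], coef)
        else:
            b0 = b[0]
        return self._results(
            intercept=b0,
            coef=coef,
            selected=[names[t] for t in terms],
            cv_risk=mean_risk,
            rss=rss,
            move_log=state.move_log,
            per_size_best={
                s: ([names[t] for t in tm], r) for s, (tm, r) in sorted(state.best.items())
            },
        )


def dsa_search(ps, y, config: DsaConfig | None = None) -> SelectionResults:
    """Functional wrapper around :class:`DsaSelect`."""
    config = config or DsaConfig()
    return DsaSelect(y, ps).fit(config=config)
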