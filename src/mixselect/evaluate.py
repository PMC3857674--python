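"""Replicate evaluation harness.

Runs any of the selection/estimation methods over R simulated replicates of
a scenario and assembles the standard performance measures:

* per predictor: mean estimate (unconditional — zeros counted when a term
  is unselected — with a conditional-on-selection mean reported alongside),
  empirical SE (SD of estimates across replicates), inclusion frequency,
  and MSE against the true coefficient;
* per method: average model size, false positive rate (average fraction of
  truly-null terms selected per replicate) and true positive rate
  (likewise over truly-nonzero terms).

Replicate r of an experiment uses seed base_seed + r for data generation,
with cross-validation folds drawn from a stream derived from the same seed,
so runs are reproducible and independent of any parallelism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .averaging import BmaSelect
from .base import SelectionResults
from .design import PredictorSet, expand_predictors
from .dsa import DsaSelect
from .pls import KernelPLS
from .shrinkage import LassoSelect
from .simulate import ScenarioConfig, SimulatedData
from .spca import SupervisedPCA
from .tree import RegressionTreeScreen

__all__ = ["ReplicateSummary", "run_experiment", "compute_metrics", "METHODS"]

METHODS = {
    "lasso": LassoSelect,
    "bma": BmaSelect,
    "dsa": DsaSelect,
    "spca": SupervisedPCA,
    "plsr": KernelPLS,
    "cart": RegressionTreeScreen,
}

@dataclass
class ReplicateSummary:
    """Aggregated performance of one method over R replicates."""

    method: str
    n_replicates: int
    table: pd.DataFrame  # per-predictor summary
    avg_model_size: float
    fpr: float
    tpr: float

    def nonzero_table(self) -> pd.DataFrame:
        return self.table[self.table["true_beta"] != 0.0]

    def to_markdown(self) -> str:
        t = self.nonzero_table()
        lines = [
            f"### {self.method} (R={self.n_replicates})",
            "",
            "| Predictor | beta | Estimate (ESE) | Percent included |",
            "|---|---|---|---|",
        ]
        for name, row in t.iterrows():
            lines.append(
                f"| {name} | {row['true_beta']:.2f} | "
                f"{row['mean_estimate']:.2f} ({row['ese']:.2f}) | "
                f"{100 * row['inclusion_freq']:.1f}% |"
            )
        lines += [
            "",
            f"Average model size: {self.avg_model_size:.1f}  |  "
            f"FPR: {self.fpr:.3f}  |  TPR: {self.tpr:.3f}",
        ]
        return "\n".join(lines)


def compute_metrics(results: list[SelectionResults], true_beta: np.ndarray,
                    names: list[str] | None = None) -> ReplicateSummary:
    """Summarize a list of per-replicate fits against the true coefficients.

    Definitions: inclusion frequency is the fraction of replicates selecting
    a term; FPR (TPR) is the mean over replicates of the fraction of
    truly-null (truly-nonzero) terms selected; MSE_p averages
    (betahat_p - beta_p)^2 with betahat_p = 0 when unselected.
    """
    if not results:
        raise ValueError("need at least one replicate")
    if names is None:
        names = results[0].names
    true_beta = np.asarray(true_beta, dtype=float)
    R = len(results)
    P = len(names)
    est = np.zeros((R, P))
    sel = np.zeros((R, P), dtype=bool)
    sizes = np.zeros(R)
    name_idx = {nm: i for i, nm in enumerate(names)}
    for r, res in enumerate(results):
        for nm, b in res.params.items():
            est[r, name_idx[nm]] = b
        for nm in res.selected:
            sel[r, name_idx[nm]] = True
        sizes[r] = res.model_size

    null_mask = true_beta == 0.0
    nz_mask = ~null_mask
    fpr = float(sel[:, null_mask].mean()) if null_mask.any() else np.nan
    tpr = float(sel[:, nz_mask].mean()) if nz_mask.any() else np.nan

    with np.errstate(invalid="ignore"):
        cond_mean = np.where(
            sel.sum(axis=0) > 0,
            np.divide(
                (est * sel).sum(axis=0), np.maximum(sel.sum(axis=0), 1)
            ),
            np.nan,
        )
    table = pd.DataFrame(
        {
            "true_beta": true_beta,
            "mean_estimate": est.mean(axis=0),
            "mean_estimate_selected": cond_mean,
            "ese": est.std(axis=0, ddof=1) if R > 1 else np.zeros(P),
            "inclusion_freq": sel.mean(axis=0),
            "mse": ((est - true_beta) ** 2).mean(axis=0),
        },
        index=names,
    )
    return ReplicateSummary(
        method=results[0].method if results else "",
        n_replicates=R,
        table=table,
        avg_model_size=float(sizes.mean()),
        fpr=fpr,
        tpr=tpr,
    )


def _check_compat(method: str, family: str) -> None:
    cls = METHODS[method]
    if family not in cls.supported_families:
        raise ValueError(
            f"method {method!r} does not support the {family!r} outcome family"
        )


def fit_method(method: str, data: SimulatedData, ps: PredictorSet, seed,
               **fit_kw) -> SelectionResults:
    """Fit one named method on one dataset (CV streams derived from seed)."""
    cls = METHODS[method]
    model = cls(data.y, ps, family=data.family,
                offset=data.offset if data.family == "poisson" else None)
    kw = dict(fit_kw)
    if method != "bma":  # BMA is deterministic, no CV stream
        kw.setdefault("seed", seed)
    return model.fit(**kw)


def run_experiment(config: ScenarioConfig, methods: list[str],
                   n_replicates: int | None = None, two_step: bool = False,
                   method_kw: dict | None = None,
                   progress: bool = False) -> dict[str, ReplicateSummary]:
    """Run the listed methods over R replicates of a scenario.

    With ``two_step=True`` a CART screen on the raw exposures precedes each
    method: the screened exposures are re-expanded into mains plus pairwise
    interactions and the method runs on that reduced candidate set
    (continuous outcomes only).  Metrics are always computed on the full
    candidate basis, with screened-out terms counted as unselected.
    """
    methods = list(methods)
    if not methods:
        raise ValueError("empty method list")
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}")
        _check_compat(m, config.family)
    if two_step and config.family != "gaussian":
        raise ValueError("the two-step CART strategy requires a continuous outcome")
    R = n_replicates or config.n_replicates
    method_kw = method_kw or {}

    full_names: list[str] | None = None
    collected: dict[str, list[SelectionResults]] = {m: [] for m in methods}
    true_beta = None
    for r in range(R):
        seed = config.replicate_seed(r)
        data = config.simulate(seed)
        ps_full = data.predictors()
        if full_names is None:
            full_names = ps_full.names
            true_beta = ps_full.true_beta
        cv_seed = np.random.SeedSequence([int(seed), 0x5EED]).generate_state(1)[0] % (2**31 - 1)
        if two_step:
            screen = RegressionTreeScreen(data.y, ps_full).fit(seed=cv_seed)
            kept = [nm for nm in data.exposure_names if nm in set(screen.selected)]
            ps_used = (
                expand_predictors(data.X[kept], true_coef={
                    k: v for k, v in data.true_coef.items()
                    if all(p in kept for p in ps_full.parents[k])
                })
                if kept else None
            )
        else:
            ps_used = ps_full
        for m in methods:
            if ps_used is None:  # screen removed everything
                collected[m].append(_empty_result(m, data, ps_full))
                continue
            res = fit_method(m, data, ps_used, cv_seed, **method_kw.get(m, {}))
            collected[m].append(res)
        if progress and (r + 1) % 25 == 0:
            print(f"  replicate {r + 1}/{R}", flush=True)

    out = {}
    for m in methods:
        out[m] = compute_metrics(collected[m], true_beta, names=full_names)
        out[m].method = m
    return out


def _empty_result(method: str, data: SimulatedData, ps: PredictorSet):
    from .base import SelectionResults

    return SelectionResults(
        method=method,
        model=None,
        intercept=float(np.mean(data.y)),
        params=pd.Series(np.zeros(ps.P), index=ps.names),
        selected=[],
        model_size=0,
    )


def summaries_to_markdown(summaries: dict[str, ReplicateSummary]) -> str:
    return "\n\n".join(s.to_markdown() for s in summaries.values())
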