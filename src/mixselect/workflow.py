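"""Generic real-data-style analysis pipeline for tabular studies.

The six-step procedure applied to any CSV-style table:

1. residualize the outcome on forced covariates (or, for counts, fit a
   confounder-only Poisson model whose fitted means become the offset);
2. prefilter collinear exposures — within each exposure group, connected
   components of the Pearson-correlation graph above a cutoff (default
   0.60) keep only the member with the smallest univariate p-value;
3. CART screen of the retained exposures;
4. expand the screened exposures into mains + pairwise interactions and run
   the requested selection methods;
5. fit an omnibus model on the union of all selections (plus forced
   covariates);
6. backward-eliminate predictors with p-value above a cutoff (default
   0.05), one at a time, largest p first; covariates are never removed.

Post-selection p-values are optimistic; the run log carries that caveat.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .design import expand_predictors
from .evaluate import METHODS, fit_method
from .simulate import SimulatedData
from .tree import fit_tree, screen_variables

__all__ = [
    "WorkflowConfig",
    "WorkflowResult",
    "residualize",
    "collinearity_prefilter",
    "omnibus_and_prune",
    "run_workflow",
]

_CAVEAT = (
    "post-selection p-values are optimistic; interpret the pruned model "
    "with that caveat in mind"
)


@dataclass
class WorkflowConfig:
    outcome: str
    exposures: list
    covariates: list = field(default_factory=list)
    groups: dict | None = None  # exposure name -> group label
    correlation_cutoff: float = 0.60
    significance_cutoff: float = 0.05
    methods: list = field(default_factory=lambda: ["lasso", "bma", "spca", "dsa"])
    family: str = "gaussian"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "WorkflowConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)

    def __post_init__(self):
        if not 0 < self.correlation_cutoff < 1:
            raise ValueError("correlation cutoff must lie in (0, 1)")
        if not 0 < self.significance_cutoff < 1:
            raise ValueError("significance cutoff must lie in (0, 1)")
        overlap = ({self.outcome} & set(self.exposures)) | (
            set(self.exposures) & set(self.covariates)
        ) | ({self.outcome} & set(self.covariates))
        if overlap:
            raise ValueError(f"columns used in more than one role: {sorted(overlap)}")


@dataclass
class WorkflowResult:
    config: WorkflowConfig
    retained_exposures: list
    screened_exposures: list
    selections: dict  # method -> selected term list
    final_model: pd.DataFrame  # term, coef, se, pvalue
    log: dict

    def to_json(self) -> str:
        return json.dumps(self.log, indent=1, default=str)


def residualize(table: pd.DataFrame, config: WorkflowConfig):
    """First-stage confounder adjustment.

    Gaussian: OLS of the outcome on the forced covariates; returns the
    residuals (the centered outcome when there are no covariates).
    Poisson: confounder-only Poisson fit; returns (counts, fitted means)
    where the fitted means serve as the second-stage offset.
    """
    y = table[config.outcome].to_numpy(dtype=float)
    if config.family == "gaussian":
        if not config.covariates:
            return y - y.mean()
        X = sm.add_constant(table[config.covariates].to_numpy(dtype=float))
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("covariate matrix is rank deficient")
        fit = sm.OLS(y, X).fit()
        return y - fit.fittedvalues
    X = sm.add_constant(
        table[config.covariates].to_numpy(dtype=float)
        if config.covariates else np.empty((y.size, 0))
    , has_constant="add")
    fit = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    return y, np.asarray(fit.fittedvalues)


def _univariate_pvalues(table: pd.DataFrame, response, config: WorkflowConfig,
                        offset=None) -> pd.Series:
    out = {}
    for col in config.exposures:
        X = sm.add_constant(table[[col]].to_numpy(dtype=float))
        if config.family == "gaussian":
            fit = sm.OLS(response, X).fit()
        else:
            fit = sm.GLM(
                response, X, family=sm.families.Poisson(),
                offset=np.log(offset),
            ).fit()
        out[col] = float(fit.pvalues[1])
    return pd.Series(out)


def collinearity_prefilter(table: pd.DataFrame, response, config: WorkflowConfig,
                           offset=None) -> list:
    """Keep one exposure per highly-correlated cluster, per group.

    Clusters are connected components of the |Pearson r| > cutoff graph,
    formed within each exposure group; the member with the smallest
    univariate p-value survives (ties: first in column order).
    """
    if not config.exposures:
        raise ValueError("need at least one exposure")
    pvals = _univariate_pvalues(table, response, config, offset)
    groups = config.groups or {e: "all" for e in config.exposures}
    retained: list = []
    for grp in dict.fromkeys(groups.get(e, "all") for e in config.exposures):
        members = [e for e in config.exposures if groups.get(e, "all") == grp]
        corr = table[members].corr().abs().to_numpy()
        # union-find over the correlation graph
        parent = list(range(len(members)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if corr[i, j] > config.correlation_cutoff:
                    parent[find(j)] = find(i)
        comps: dict[int, list] = {}
        for i in range(len(members)):
            comps.setdefault(find(i), []).append(members[i])
        for comp in comps.values():
            best = min(comp, key=lambda e: (pvals[e], config.exposures.index(e)))
            retained.append(best)
    return [e for e in config.exposures if e in set(retained)]


def omnibus_and_prune(terms: list, table: pd.DataFrame, response,
                      config: WorkflowConfig, offset=None,
                      design: pd.DataFrame | None = None):
    """Fit the omnibus model on the union of selected terms and iteratively
    remove the largest-p term above the significance cutoff (forced
    covariates are never candidates for removal)."""
    if not terms:
        raise ValueError("union of selections is empty")
    terms = list(dict.fromkeys(terms))
    n_cov = len(config.covariates)
    steps = []
    while True:
        cols = [table[c].to_numpy(dtype=float) for c in config.covariates]
        for t in terms:
            if design is not None and t in design:
                cols.append(design[t].to_numpy(dtype=float))
            elif "*" in t:
                a, b = t.split("*")
                cols.append(table[a].to_numpy(dtype=float) * table[b].to_numpy(dtype=float))
            else:
                cols.append(table[t].to_numpy(dtype=float))
        X = sm.add_constant(np.column_stack(cols))
        if config.family == "gaussian":
            fit = sm.OLS(response, X).fit()
        else:
            fit = sm.GLM(
                response, X, family=sm.families.Poisson(),
                offset=np.log(offset),
            ).fit()
        pv = pd.Series(np.asarray(fit.pvalues[1 + n_cov:]), index=terms)
        worst = pv.idxmax()
        if pv[worst] <= config.significance_cutoff or len(terms) == 1:
            final = pd.DataFrame(
                {
                    "coef": np.asarray(fit.params[1 + n_cov:]),
                    "se": np.asarray(fit.bse[1 + n_cov:]),
                    "pvalue": pv.to_numpy(),
                },
                index=terms,
            )
            if pv[worst] > config.significance_cutoff:
                # a single remaining non-significant term is still dropped
                steps.append({"removed": worst, "pvalue": float(pv[worst])})
                final = final.drop(index=worst)
            return final, steps
        steps.append({"removed": worst, "pvalue": float(pv[worst])})
        terms = [t for t in terms if t != worst]


def run_workflow(table: pd.DataFrame, config: WorkflowConfig) -> WorkflowResult:
    """Execute the full six-step pipeline on a tabular dataset."""
    offset = None
    if config.family == "gaussian":
        response = residualize(table, config)
    else:
        response, offset = residualize(table, config)

    retained = collinearity_prefilter(table, response, config, offset)

    tree = fit_tree(
        table[retained], response if config.family == "gaussian" else np.asarray(response, float),
        seed=config.seed,
    ) if config.family == "gaussian" else None
    screened = sorted(screen_variables(tree)) if tree is not None else retained
    if not screened:
        screened = retained  # fall back to the prefiltered set

    ps = expand_predictors(table[screened])
    data = SimulatedData(
        X=table[screened], y=np.asarray(response, dtype=float)
        if config.family == "gaussian" else np.asarray(response, dtype=float),
        offset=offset, family=config.family, true_coef={},
    )
    selections = {}
    for m in config.methods:
        if config.family not in METHODS[m].supported_families:
            continue
        res = fit_method(m, data, ps, seed=config.seed)
        selections[m] = list(res.selected)

    union = [t for t in ps.names if any(t in s for s in selections.values())]
    if not union:
        union = list(screened)
    final, steps = omnibus_and_prune(
        union, table, response, config, offset, design=ps.Z
    )
    log = {
        "config": {
            k: v for k, v in vars(config).items() if not k.startswith("_")
        },
        "retained_exposures": retained,
        "screened_exposures": screened,
        "selections": selections,
        "elimination_steps": steps,
        "caveat": _CAVEAT,
    }
    return WorkflowResult(
        config=config,
        retained_exposures=retained,
        screened_exposures=screened,
        selections=selections,
        final_model=final,
        log=log,
    )
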