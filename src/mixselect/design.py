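"""Candidate predictor expansion: main effects plus all pairwise interactions.

A multipollutant health-risk model with K exposures considers the design

    Z = (X1, ..., XK, X1*X2, ..., X(K-1)*XK)

of P = K + K(K-1)/2 candidate terms.  :class:`PredictorSet` carries the
expanded matrix together with term metadata (kind, parent exposures) and the
true-coefficient map used by the simulation harness, and records any
standardization applied so that fitted coefficients can always be reported on
the original Z scale.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PredictorSet", "expand_predictors", "standardize"]


@dataclass
class PredictorSet:
    """Expanded candidate design with term metadata.

    Attributes
    ----------
    Z : pandas.DataFrame
        n x P design, columns ordered mains first, then interactions
        "Xi*Xj" lexicographically with i < j.
    kind : pandas.Series
        "main" or "interaction" per column.
    parents : dict
        Column name -> tuple of parent exposure names (length 1 or 2).
    true_beta : numpy.ndarray
        Length-P true coefficients aligned with ``Z.columns`` (zeros allowed).
    scale_mean, scale_sd : numpy.ndarray or None
        Per-column centering/scaling applied to ``Z`` (None if raw).
    """

    Z: pd.DataFrame
    kind: pd.Series
    parents: dict
    true_beta: np.ndarray
    scale_mean: np.ndarray | None = None
    scale_sd: np.ndarray | None = None
    _true_coef_map: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if len(set(self.Z.columns)) != self.Z.shape[1]:
            raise ValueError("duplicate predictor names")
        if len(self.true_beta) != self.Z.shape[1]:
            raise ValueError("true_beta misaligned with design columns")

    @property
    def names(self) -> list[str]:
        return list(self.Z.columns)

    @property
    def n(self) -> int:
        return self.Z.shape[0]

    @property
    def P(self) -> int:
        return self.Z.shape[1]

    @property
    def exposure_names(self) -> list[str]:
        return [c for c in self.Z.columns if self.kind[c] == "main"]

    @property
    def is_standardized(self) -> bool:
        return self.scale_sd is not None

    @property
    def true_nonzero(self) -> list[str]:
        return [c for c, b in zip(self.Z.columns, self.true_beta) if b != 0.0]

    def values(self) -> np.ndarray:
        return self.Z.to_numpy()

    def destandardize_coef(
        self, intercept: float, coef: np.ndarray
    ) -> tuple[float, np.ndarray]:
        """Map (intercept, coefficients) fitted on the stored (possibly
        standardized) design back to the original Z scale."""
        coef = np.asarray(coef, dtype=float)
        if not self.is_standardized:
            return float(intercept), coef
        b = coef / self.scale_sd
        b0 = float(intercept - np.sum(b * self.scale_mean))
        return b0, b

    def subset(self, names: list[str]) -> "PredictorSet":
        """Restrict to a subset of columns (order preserved)."""
        idx = [self.Z.columns.get_loc(c) for c in names]
        return PredictorSet(
            Z=self.Z[names].copy(),
            kind=self.kind[names],
            parents={c: self.parents[c] for c in names},
            true_beta=self.true_beta[idx],
            scale_mean=None if self.scale_mean is None else self.scale_mean[idx],
            scale_sd=None if self.scale_sd is None else self.scale_sd[idx],
            _true_coef_map=self._true_coef_map,
        )

    def to_csv(self, path, sidecar_path=None) -> None:
        """Write the design as CSV with a JSON sidecar of term metadata."""
        self.Z.to_csv(path, index=False)
        if sidecar_path is not None:
            meta = {
                "names": self.names,
                "kind": self.kind.tolist(),
                "parents": {k: list(v) for k, v in self.parents.items()},
                "true_beta": self.true_beta.tolist(),
            }
            with open(sidecar_path, "w") as fh:
                json.dump(meta, fh, indent=1)


def interaction_name(a: str, b: str) -> str:
    return f"{a}*{b}"


def expand_predictors(
    X: pd.DataFrame | np.ndarray,
    true_coef: dict | None = None,
    exposure_names: list[str] | None = None,
) -> PredictorSet:
    """Expand raw exposures into mains + all pairwise interaction products.

    Parameters
    ----------
    X : DataFrame or ndarray
        n x K raw exposures.  Array input gets names "X1"..."XK".
    true_coef : dict, optional
        Map from term name (e.g. ``"X2"`` or ``"X2*X3"``) to its true
        coefficient in the generating model; missing terms are zero.

    Interaction columns are elementwise products of the *raw* parent
    exposures, matching the generating model's parameterization.
    """
    if not isinstance(X, pd.DataFrame):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        cols = exposure_names or [f"X{i + 1}" for i in range(X.shape[1])]
        X = pd.DataFrame(X, columns=cols)
    if len(set(X.columns)) != X.shape[1]:
        raise ValueError("duplicate exposure names")
    true_coef = dict(true_coef or {})

    cols: dict[str, np.ndarray] = {}
    kind: dict[str, str] = {}
    parents: dict[str, tuple] = {}
    for c in X.columns:
        cols[c] = X[c].to_numpy(dtype=float)
        kind[c] = "main"
        parents[c] = (c,)
    for a, b in itertools.combinations(X.columns, 2):
        name = interaction_name(a, b)
        cols[name] = cols[a] * cols[b]
        kind[name] = "interaction"
        parents[name] = (a, b)

    names = list(cols)
    # normalize "Xj*Xi" keys in true_coef to the stored i<j order
    tc = {}
    for key, val in true_coef.items():
        if key in cols:
            tc[key] = val
        elif "*" in key:
            a, b = key.split("*")
            alt = interaction_name(b, a)
            if alt not in cols:
                raise KeyError(f"unknown interaction term {key!r}")
            tc[alt] = val
        else:
            raise KeyError(f"unknown predictor {key!r}")
    beta = np.array([tc.get(c, 0.0) for c in names], dtype=float)

    return PredictorSet(
        Z=pd.DataFrame(cols),
        kind=pd.Series(kind),
        parents=parents,
        true_beta=beta,
        _true_coef_map=tc,
    )


def standardize(ps: PredictorSet, mode: str = "zscore") -> PredictorSet:
    """Return a copy with columns scaled to mean 0, SD 1 (``mode="zscore"``)
    or unchanged (``mode="none"``).  The transform is recorded so fitted
    coefficients can be reported on the original scale."""
    if mode == "none":
        return ps
    if mode != "zscore":
        raise ValueError(f"unknown standardization mode {mode!r}")
    if ps.n < 2:
        raise ValueError("need at least 2 rows to standardize")
    V = ps.Z.to_numpy()
    mean = V.mean(axis=0)
    sd = V.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = [ps.names[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance columns: {bad}")
    Zs = pd.DataFrame((V - mean) / sd, columns=ps.Z.columns, index=ps.Z.index)
    return PredictorSet(
        Z=Zs,
        kind=ps.kind,
        parents=ps.parents,
        true_beta=ps.true_beta,
        scale_mean=mean,
        scale_sd=sd,
        _true_coef_map=ps._true_coef_map,
    )
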