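"""Common Model/Results machinery for the selection and estimation methods.

Every method follows the same pattern: build a model object from the
response and a :class:`~mixselect.design.PredictorSet`, call ``fit()``, and
get back a :class:`SelectionResults` carrying dense coefficient estimates on
the original Z scale, the selected-term set, the model size and method
metadata, with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .design import PredictorSet

__all__ = ["SelectionModel", "SelectionResults", "seeded_kfold"]


def seeded_kfold(n_splits: int, seed) -> KFold:
    """Shuffled K-fold splitter with a reproducible fold assignment."""
    rs = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31 - 1))
    return KFold(n_splits=n_splits, shuffle=True, random_state=rs)


class SelectionModel:
    """Base class: holds the response, the candidate design, the outcome
    family and (for counts) the offset.

    Parameters
    ----------
    endog : array-like
        Response vector (continuous, or nonnegative integer counts for
        ``family="poisson"``).
    predictors : PredictorSet
        Candidate design Z.
    family : str
        "gaussian" or "poisson".
    offset : array-like, optional
        Strictly positive expected counts entering the Poisson log link as
        ``log(offset)``; required for the Poisson family.
    """

    #: families the concrete method supports
    supported_families: tuple = ("gaussian", "poisson")
    method_name: str = "base"

    def __init__(self, endog, predictors: PredictorSet, family: str = "gaussian",
                 offset=None):
        self.endog = np.asarray(endog, dtype=float)
        if self.endog.ndim != 1 or self.endog.size != predictors.n:
            raise ValueError("endog must be a vector matching the design rows")
        if family not in ("gaussian", "poisson"):
            raise ValueError(f"unknown family {family!r}")
        if family not in self.supported_families:
            raise ValueError(
                f"{type(self).__name__} does not support the {family!r} family"
            )
        if family == "poisson":
            if np.any(self.endog < 0) or np.any(self.endog != np.round(self.endog)):
                raise ValueError("poisson family requires nonnegative integer counts")
            if offset is None:
                offset = np.ones_like(self.endog)
            offset = np.asarray(offset, dtype=float)
            if np.any(offset <= 0):
                raise ValueError("offset must be strictly positive")
        self.predictors = predictors
        self.family = family
        self.offset = None if family == "gaussian" else offset

    @property
    def nobs(self) -> int:
        return self.endog.size

    def fit(self, **kwargs) -> "SelectionResults":  # pragma: no cover - abstract
        raise NotImplementedError

    def _results(self, intercept, coef, selected, model_size=None, **extras):
        names = self.predictors.names
        coef = pd.Series(np.asarray(coef, dtype=float), index=names)
        selected = [s for s in names if s in set(selected)]
        if model_size is None:
            model_size = len(selected)
        return SelectionResults(
            method=self.method_name,
            model=self,
            intercept=float(intercept),
            params=coef,
            selected=selected,
            model_size=int(model_size),
            info=dict(extras),
        )


@dataclass
class SelectionResults:
    """Fit of one method on one dataset.

    ``params`` is dense on the Z basis (zeros for unselected terms) and is
    always on the original, unstandardized scale.  ``model_size`` is the
    number of selected non-intercept terms, except for methods that use
    every predictor by construction (partial least squares), where it is P.
    """

    method: str
    model: SelectionModel
    intercept: float
    params: pd.Series
    selected: list
    model_size: int
    info: dict = field(default_factory=dict)

    @property
    def names(self) -> list:
        return list(self.params.index)

    def coef_array(self) -> np.ndarray:
        return self.params.to_numpy()

    def predict_linear(self, Z: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(Z, dtype=float) @ self.coef_array()

    def summary(self) -> str:
        lines = [
            f"{self.method} selection results",
            "=" * 46,
            f"n = {self.model.nobs}, P = {self.params.size}, "
            f"family = {self.model.family}",
            f"model size = {self.model_size}",
            "-" * 46,
            f"{'term':<14}{'coef':>12}  selected",
        ]
        sel = set(self.selected)
        for name, b in self.params.items():
            if b != 0.0 or name in sel:
                lines.append(f"{name:<14}{b:>12.4f}  {'*' if name in sel else ''}")
        for k, v in self.info.items():
            if np.isscalar(v):
                lines.append(f"{k}: {v}")
        return "\n".join(lines)
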