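"""Logistic-regression core: predictor encoding, fitting, prediction.

The prediction model at the center of the framework is an ordinary
maximum-likelihood logistic regression of favorable outcome on six
predictors, with the encoding used for the SAHIT outcome model:

* ``age``           linear, in years
* ``wfns_high``     binary, WFNS grade IV-V (vs I-III)
* ``hypertension``  binary, premorbid hypertension
* ``fisher``        CT Fisher grade 1-4, dummy-coded with grade 1 reference
* ``size_large``    binary, aneurysm >= 13 mm
* ``location``      aneurysm site, 6 categories dummy-coded with ACA
                    reference

Fitting is delegated to ``statsmodels`` (IRLS); this module adds the fixed
encoding, offset support (needed for calibration intercepts), degenerate
outcome / separation detection, and JSON serialization so externally fitted
models can be validated without refitting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "LOCATIONS",
    "FISHER_GRADES",
    "ModelSpec",
    "FittedModel",
    "DegenerateOutcomeError",
    "SeparationError",
    "SchemaError",
    "fit_logistic",
    "fit_model",
    "predict_prob",
]

LOCATIONS = ("ACA", "ACOM", "ICA", "MCA", "PCOM", "Posterior")
FISHER_GRADES = (1, 2, 3, 4)

#: |linear predictor| is clipped here before exponentiation
_LP_CAP = 700.0

#: |coefficient| beyond this (log-odds) is treated as monotone likelihood
_SEPARATION_BOUND = 15.0


class DegenerateOutcomeError(ValueError):
    """Outcome vector contains only one class; the MLE does not exist."""


class SeparationError(RuntimeError):
    """A covariate perfectly separates the outcome (monotone likelihood)."""


class SchemaError(ValueError):
    """Input rows do not match the model's predictor encoding."""


@dataclass(frozen=True)
class ModelSpec:
    """Fixed predictor encoding producing a deterministic design matrix.

    Reference levels (Fisher grade 1, location ACA) are part of the
    encoding and recorded in serialized models.
    """

    predictors: tuple = ("age", "wfns_high", "hypertension", "fisher",
                         "size_large", "location")
    fisher_reference: int = 1
    location_reference: str = "ACA"

    @property
    def column_names(self) -> list:
        names = []
        for p in self.predictors:
            if p == "fisher":
                names += [f"fisher_{g}" for g in FISHER_GRADES
                          if g != self.fisher_reference]
            elif p == "location":
                names += [f"location_{l}" for l in LOCATIONS
                          if l != self.location_reference]
            else:
                names.append(p)
        return names

    def design_matrix(self, df: pd.DataFrame) -> np.ndarray:
        """Encode predictor columns of ``df`` into a float design matrix.

        Raises :class:`SchemaError` on missing columns, NA values, or
        categories outside the encoding.
        """
        missing = [p for p in self.predictors if p not in df.columns]
        if missing:
            raise SchemaError(f"missing predictor columns: {missing}")
        sub = df[list(self.predictors)]
        if sub.isna().any().any():
            bad = sub.columns[sub.isna().any()].tolist()
            raise SchemaError(
                f"NA values in predictor columns {bad}; impute upstream"
            )
        cols = []
        for p in self.predictors:
            if p == "fisher":
                vals = sub[p].astype(int).to_numpy()
                if not np.isin(vals, FISHER_GRADES).all():
                    raise SchemaError("fisher grade outside 1-4")
                for g in FISHER_GRADES:
                    if g != self.fisher_reference:
                        cols.append((vals == g).astype(float))
            elif p == "location":
                vals = sub[p].astype(str).to_numpy()
                unknown = set(vals) - set(LOCATIONS)
                if unknown:
                    raise SchemaError(f"unknown location level(s) {unknown}")
                for l in LOCATIONS:
                    if l != self.location_reference:
                        cols.append((vals == l).astype(float))
            else:
                cols.append(sub[p].to_numpy(dtype=float))
        return np.column_stack(cols)


@dataclass
class FittedModel:
    """A fitted logistic model: encoding spec + intercept + coefficients."""

    intercept: float
    beta: np.ndarray
    column_names: list
    spec: Optional[ModelSpec] = None
    converged: bool = True
    cov: Optional[np.ndarray] = None
    n_obs: int = 0
    meta: dict = field(default_factory=dict)

    def linear_predictor(self, X: np.ndarray,
                         offset: Optional[np.ndarray] = None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.beta.size:
            raise SchemaError(
                f"design has {X.shape[1] if X.ndim == 2 else '?'} columns, "
                f"model expects {self.beta.size}"
            )
        lp = self.intercept + X @ self.beta
        if offset is not None:
            lp = lp + np.asarray(offset, dtype=float)
        return lp

    def predict(self, X: np.ndarray,
                offset: Optional[np.ndarray] = None) -> np.ndarray:
        return _expit(self.linear_predictor(X, offset))

    def predict_df(self, df: pd.DataFrame) -> np.ndarray:
        if self.spec is None:
            raise SchemaError("model carries no predictor encoding spec")
        return self.predict(self.spec.design_matrix(df))

    def lp_df(self, df: pd.DataFrame) -> np.ndarray:
        if self.spec is None:
            raise SchemaError("model carries no predictor encoding spec")
        return self.linear_predictor(self.spec.design_matrix(df))

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "intercept": self.intercept,
            "beta": list(map(float, self.beta)),
            "column_names": list(self.column_names),
            "converged": self.converged,
            "n_obs": int(self.n_obs),
            "meta": self.meta,
        }
        if self.spec is not None:
            payload["spec"] = {
                "predictors": list(self.spec.predictors),
                "fisher_reference": self.spec.fisher_reference,
                "location_reference": self.spec.location_reference,
            }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FittedModel":
        d = json.loads(text)
        spec = None
        if "spec" in d:
            spec = ModelSpec(
                predictors=tuple(d["spec"]["predictors"]),
                fisher_reference=d["spec"]["fisher_reference"],
                location_reference=d["spec"]["location_reference"],
            )
        return cls(
            intercept=float(d["intercept"]),
            beta=np.asarray(d["beta"], dtype=float),
            column_names=list(d["column_names"]),
            spec=spec,
            converged=bool(d.get("converged", True)),
            n_obs=int(d.get("n_obs", 0)),
            meta=d.get("meta", {}),
        )


def _expit(lp: np.ndarray) -> np.ndarray:
    lp = np.clip(np.asarray(lp, dtype=float), -_LP_CAP, _LP_CAP)
    return 1.0 / (1.0 + np.exp(-lp))


def fit_logistic(
    X: Optional[np.ndarray],
    y: Sequence,
    offset: Optional[np.ndarray] = None,
    column_names: Optional[list] = None,
    spec: Optional[ModelSpec] = None,
) -> FittedModel:
    """ML logistic regression of ``y`` on ``X`` with an optional fixed offset.

    ``X`` may be ``None`` or have zero columns for an intercept-only
    (or offset-only) model.  Raises :class:`DegenerateOutcomeError` when
    ``y`` has a single class and :class:`SeparationError` on monotone
    likelihood (detected via statsmodels or coefficients beyond
    ``+-15`` log-odds).
    """
    y = np.asarray(y, dtype=float)
    if y.size == 0 or y.min() == y.max():
        raise DegenerateOutcomeError(
            "outcome vector has a single class; logistic MLE undefined"
        )
    if X is None:
        X = np.empty((y.size, 0))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    design = np.column_stack([np.ones(y.size), X])
    try:
        res = sm.GLM(y, design, family=sm.families.Binomial(),
                     offset=offset).fit(maxiter=200, tol=1e-10)
    except PerfectSeparationError as exc:  # pragma: no cover - version dep.
        raise SeparationError(str(exc)) from exc
    params = np.asarray(res.params, dtype=float)
    converged = bool(getattr(res, "converged", True))
    if np.max(np.abs(params)) > _SEPARATION_BOUND:
        mu = np.asarray(res.fittedvalues, dtype=float)
        at_boundary = (mu < 1e-8) | (mu > 1 - 1e-8)
        if at_boundary.all():
            raise SeparationError(
                "a covariate perfectly separates the outcome: all fitted "
                "probabilities at the boundary (monotone likelihood)"
            )
        if at_boundary.any() or not converged:
            warnings.warn(
                "quasi-separation: a coefficient exceeds +-15 log-odds "
                "(an empty covariate-by-outcome cell); estimates for the "
                "affected term are unreliable",
                RuntimeWarning, stacklevel=2)
            converged = False
    names = (list(column_names) if column_names is not None
             else [f"x{i}" for i in range(X.shape[1])])
    return FittedModel(
        intercept=float(params[0]),
        beta=params[1:],
        column_names=names,
        spec=spec,
        converged=converged,
        cov=np.asarray(res.cov_params(), dtype=float),
        n_obs=int(y.size),
    )



def fit_model(df: pd.DataFrame, spec: Optional[ModelSpec] = None,
              y_col: str = "y_favorable") -> FittedModel:
    """Fit the six-predictor outcome model on a complete data frame."""
    spec = spec or ModelSpec()
    X = spec.design_matrix(df)
    y = df[y_col].to_numpy(dtype=float)
    return fit_logistic(X, y, column_names=spec.column_names, spec=spec)


def predict_prob(model: FittedModel, X: np.ndarray,
                 offset: Optional[np.ndarray] = None):
    """Return ``(p, lp)`` for design rows under a fitted model."""
    lp = model.linear_predictor(X, offset)
    return _expit(lp), lp
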