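"""Chained-equations multiple imputation and Rubin's-rules pooling.

Missingness in the clustered repository comes in two flavors: whole
predictor columns absent in some clusters (block-missing) and item-level
missing-at-random cells.  Both are handled by multiple imputation by
chained equations over the *pooled* repository (not per cluster), with the
outcome included in every conditional model.  Per-variable conditionals:

* continuous (age): Bayesian linear regression — residual variance drawn
  from its scaled inverse-chi-square posterior, coefficients from their
  normal posterior, imputations drawn with residual noise (predictive-mean
  matching available as an option);
* binary: logistic regression with coefficients drawn from the asymptotic
  normal posterior, imputations drawn Bernoulli;
* categorical (Fisher grade, aneurysm location): ridge-stabilized
  multinomial logistic regression, imputations drawn from the predicted
  category probabilities.

Performance estimates computed on each completed dataset are combined with
Rubin's rules: pooled point estimate = mean, total variance
T = W̄ + (1 + 1/m) B, with concordance statistics pooled on the logit
scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.linear_model import LogisticRegression

from .dataset import ClusteredDataset
from .glm import FISHER_GRADES, LOCATIONS

__all__ = ["ImputationSet", "RubinPooled", "mice_fit", "rubin_pool"]

_BINARY = ("wfns_high", "hypertension", "size_large")
_CATEGORICAL = {"fisher": [float(g) for g in FISHER_GRADES],
                "location": list(LOCATIONS)}
_CONTINUOUS = ("age",)
_MODEL_VARS = _CONTINUOUS + _BINARY + tuple(_CATEGORICAL)


@dataclass
class ImputationSet:
    """m completed copies of a dataset plus imputation provenance."""

    m: int
    datasets: list
    methods: dict
    iterations: int
    seed: int
    variables: list = field(default_factory=list)


@dataclass
class RubinPooled:
    pooled: float
    total_var: float
    within: float
    between: float
    m: int
    transform: str = "identity"

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_var))


def _encode_predictors(df: pd.DataFrame, exclude: str) -> np.ndarray:
    """Design matrix from every model variable except ``exclude`` plus y."""
    cols = []
    for v in _MODEL_VARS:
        if v == exclude:
            continue
        if v in _CATEGORICAL:
            levels = _CATEGORICAL[v]
            vals = df[v].to_numpy()
            for lev in levels[1:]:
                cols.append((vals == lev).astype(float))
        else:
            cols.append(df[v].to_numpy(dtype=float))
    cols.append(df["y_favorable"].to_numpy(dtype=float))
    return np.column_stack(cols)


def _impute_continuous(df, var, obs, rng, pmm: bool):
    X = _encode_predictors(df, var)
    Xo = np.column_stack([np.ones(obs.sum()), X[obs]])
    yo = df.loc[obs, var].to_numpy(dtype=float)
    XtX = Xo.T @ Xo + 1e-8 * np.eye(Xo.shape[1])
    beta_hat = np.linalg.solve(XtX, Xo.T @ yo)
    resid = yo - Xo @ beta_hat
    dof = max(Xo.shape[0] - Xo.shape[1], 1)
    sigma2 = resid @ resid / rng.chisquare(dof)
    L = np.linalg.cholesky(np.linalg.inv(XtX) * sigma2)
    beta = beta_hat + L @ rng.standard_normal(beta_hat.size)
    Xm = np.column_stack([np.ones((~obs).sum()), X[~obs]])
    pred = Xm @ beta
    if pmm:
        fit_obs = Xo @ beta_hat
        idx = np.abs(fit_obs[None, :] - (Xm @ beta_hat)[:, None]).argsort(
            axis=1)[:, :5]
        pick = idx[np.arange(idx.shape[0]), rng.integers(0, 5, idx.shape[0])]
        return yo[pick]
    return pred + rng.standard_normal(pred.size) * np.sqrt(sigma2)


def _impute_binary(df, var, obs, rng):
    X = _encode_predictors(df, var)
    yo = df.loc[obs, var].to_numpy(dtype=float)
    if yo.min() == yo.max():  # observed part is constant: propagate it
        return np.full((~obs).sum(), yo[0])
    clf = LogisticRegression(C=1e4, max_iter=2000)
    clf.fit(X[obs], yo)
    lp = clf.decision_function(X[~obs])
    # approximate parameter draw: perturb the linear predictor with the
    # binomial-information scale of the fit
    p_obs = expit(clf.decision_function(X[obs]))
    info = max(float(np.sum(p_obs * (1 - p_obs))), 1.0)
    lp = lp + rng.standard_normal(lp.size) * np.sqrt(X.shape[1] / info)
    return (rng.random(lp.size) < expit(lp)).astype(float)


def _impute_categorical(df, var, obs, rng):
    X = _encode_predictors(df, var)
    yo = df.loc[obs, var].to_numpy()
    classes = np.unique(yo)
    if classes.size == 1:
        return np.full((~obs).sum(), classes[0])
    clf = LogisticRegression(C=1e4, max_iter=2000)
    clf.fit(X[obs], yo)
    probs = clf.predict_proba(X[~obs])
    cum = probs.cumsum(axis=1)
    u = rng.random(probs.shape[0])[:, None]
    pick = (u > cum).sum(axis=1)
    return clf.classes_[pick]


def mice_fit(data: ClusteredDataset, m: int = 5, iterations: int = 10,
             seed: int = 0, pmm_age: bool = False) -> ImputationSet:
    """Multiple imputation by chained equations on the pooled repository.

    Returns ``m`` completed datasets.  Every variable with missingness
    must have at least one observed value overall (a 100%-missing column
    is an error); data with no missingness yield ``m`` identical copies.
    """
    df0 = data.df
    targets = [v for v in _MODEL_VARS
               if v in df0.columns and df0[v].isna().any()]
    for v in targets:
        if df0[v].notna().sum() == 0:
            raise ValueError(
                f"variable {v!r} is 100% missing; it cannot be imputed")
    methods = {v: ("pmm" if (v in _CONTINUOUS and pmm_age)
                   else "bayes-linear" if v in _CONTINUOUS
                   else "logistic" if v in _BINARY
                   else "multinomial")
               for v in targets}
    if not targets:
        return ImputationSet(m=m, datasets=[data.copy() for _ in range(m)],
                             methods={}, iterations=iterations, seed=seed)

    ss = np.random.SeedSequence(seed)
    completed = []
    for child in ss.spawn(m):
        rng = np.random.default_rng(child)
        df = df0.copy()
        obs_masks = {v: df0[v].notna().to_numpy() for v in targets}
        # initialize from the observed marginal distribution
        for v in targets:
            miss = ~obs_masks[v]
            pool = df.loc[obs_masks[v], v].to_numpy()
            df.loc[miss, v] = rng.choice(pool, size=miss.sum())
        for _ in range(iterations):
            for v in targets:
                obs = obs_masks[v]
                if v in _CONTINUOUS:
                    vals = _impute_continuous(df, v, obs, rng, pmm_age)
                elif v in _BINARY:
                    vals = _impute_binary(df, v, obs, rng)
                else:
                    vals = _impute_categorical(df, v, obs, rng)
                df.loc[~obs, v] = vals
        meta = dict(data.meta)
        completed.append(ClusteredDataset(df, meta))
    return ImputationSet(m=m, datasets=completed, methods=methods,
                         iterations=iterations, seed=seed,
                         variables=targets)


def rubin_pool(estimates: Sequence[float], variances: Sequence[float],
               transform: str = "identity") -> RubinPooled:
    """Combine per-imputation estimates with Rubin's rules.

    ``variances`` are squared standard errors.  With ``transform='logit'``
    both inputs are expected on the natural scale (variances delta-method
    converted) and the pooled estimate is back-transformed.
    """
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    if est.size == 0:
        raise ValueError("need at least one imputation")
    if est.size != var.size:
        raise ValueError("estimates and variances must match in length")
    if transform == "logit":
        var = var / (est * (1 - est)) ** 2
        est = logit(est)
    elif transform != "identity":
        raise ValueError(f"unknown transform {transform!r}")
    m = est.size
    w = float(var.mean())
    b = float(est.var(ddof=1)) if m > 1 else 0.0
    t = w + (1 + 1 / m) * b
    pooled = float(est.mean())
    if transform == "logit":
        pooled = float(expit(pooled))
    return RubinPooled(pooled=pooled, total_var=t, within=w, between=b,
                       m=m, transform=transform)
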