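"""Random-effects meta-analysis of per-cluster performance estimates.

After leave-one-cluster-out cross-validation every cluster contributes one
estimate of each performance metric.  The pooled mean serves as the
reference value for overall external performance, and the I² statistic
describes the share of the total variability attributable to between-
cluster heterogeneity rather than sampling error.

Model: theta_k ~ N(mu, tau^2 + se_k^2).  tau^2 is estimated by REML
(default) or DerSimonian-Laird; the pooled mean is the inverse-variance
weighted average with weights 1/(se_k^2 + tau^2) and a Wald 95% CI
(Hartung-Knapp optional).  Cochran's Q uses fixed-effect weights and
I^2 = max(0, (Q - df)/Q) * 100.

Concordance statistics are pooled on the logit scale (the convention of
the standard meta-analysis tooling for c-statistics) with the delta-method
standard error se_logit = se_c / (c (1 - c)); calibration intercepts and
slopes are pooled on the identity scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import expit, logit
from scipy.stats import t as t_dist

__all__ = ["MetaResult", "pool", "i_squared", "se_from_ci", "forest_data"]


@dataclass
class MetaResult:
    pooled: float            # back-transformed pooled mean
    ci_low: float
    ci_high: float
    tau2: float              # between-cluster variance, transformed scale
    Q: float
    df: int
    i2: float                # percent
    transform: str
    method: str
    estimates: np.ndarray    # inputs, natural scale
    ses: np.ndarray          # inputs, transformed scale
    pooled_se: float = 0.0   # transformed scale
    extra: dict = field(default_factory=dict)


def i_squared(Q: float, df: int) -> float:
    """I² heterogeneity percentage, floored at zero."""
    if df < 1:
        raise ValueError("I² requires df >= 1")
    if Q < 0:
        raise ValueError("Q must be non-negative")
    if Q == 0:
        return 0.0
    return max(0.0, (Q - df) / Q) * 100.0


def se_from_ci(ci_low, ci_high, transform: str = "identity") -> np.ndarray:
    """Reconstruct standard errors from printed 95% CIs.

    The CI width is divided by 3.92 on the chosen analysis scale; for the
    logit transform the bounds are logit-transformed first, so asymmetry of
    the back-transformed interval is expected.
    """
    lo = np.asarray(ci_low, dtype=float)
    hi = np.asarray(ci_high, dtype=float)
    if transform == "logit":
        lo, hi = logit(lo), logit(hi)
    elif transform != "identity":
        raise ValueError(f"unknown transform {transform!r}")
    return (hi - lo) / 3.92


def _reml_tau2(theta: np.ndarray, v: np.ndarray) -> float:
    def neg_restricted_ll(tau2: float) -> float:
        w = 1.0 / (v + tau2)
        mu = np.sum(w * theta) / np.sum(w)
        return 0.5 * (np.sum(np.log(v + tau2)) + np.log(np.sum(w))
                      + np.sum(w * (theta - mu) ** 2))

    hi = max(10.0 * theta.var(), 1e-3)
    res = minimize_scalar(neg_restricted_ll, bounds=(0.0, hi),
                          method="bounded",
                          options={"xatol": 1e-10})
    return float(max(res.x, 0.0))


def pool(estimates: Sequence[float], ses: Sequence[float],
         transform: str = "identity", method: str = "REML",
         ses_on: str = "natural", hartung_knapp: bool = False) -> MetaResult:
    """Random-effects pooling of per-cluster estimates.

    Parameters
    ----------
    estimates
        Per-cluster point estimates on the natural scale (c in (0,1) when
        ``transform='logit'``).
    ses
        Standard errors; on the natural scale by default (delta-method
        converted for the logit transform), or already on the analysis
        scale when ``ses_on='transformed'`` (e.g. reconstructed from
        printed CIs with :func:`se_from_ci`).
    transform
        ``'logit'`` for concordance statistics, ``'identity'`` otherwise.
    method
        ``'REML'`` (default) or ``'DL'`` (DerSimonian-Laird).
    hartung_knapp
        Use the Hartung-Knapp variance and a t reference for the CI.
    """
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if est.size != se.size:
        raise ValueError("estimates and ses must have equal length")
    if est.size < 2:
        raise ValueError("pooling needs at least two clusters")
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")

    if transform == "logit":
        if np.any((est <= 0) | (est >= 1)):
            raise ValueError("logit transform requires estimates in (0,1)")
        theta = logit(est)
        se_t = se / (est * (1.0 - est)) if ses_on == "natural" else se
    elif transform == "identity":
        theta = est
        se_t = se
    else:
        raise ValueError(f"unknown transform {transform!r}")

    v = se_t ** 2
    k = est.size
    df = k - 1

    # Cochran's Q with fixed-effect weights
    w_fe = 1.0 / v
    mu_fe = np.sum(w_fe * theta) / np.sum(w_fe)
    Q = float(np.sum(w_fe * (theta - mu_fe) ** 2))

    if method == "DL":
        denom = np.sum(w_fe) - np.sum(w_fe ** 2) / np.sum(w_fe)
        tau2 = max(0.0, (Q - df) / denom)
    elif method == "REML":
        tau2 = _reml_tau2(theta, v)
    else:
        raise ValueError(f"unknown method {method!r}")

    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * theta) / np.sum(w))
    if hartung_knapp:
        se_mu = float(np.sqrt(np.sum(w * (theta - mu) ** 2)
                              / (df * np.sum(w))))
        crit = float(t_dist.ppf(0.975, df))
    else:
        se_mu = float(np.sqrt(1.0 / np.sum(w)))
        crit = 1.96
    lo, hi = mu - crit * se_mu, mu + crit * se_mu
    back = expit if transform == "logit" else (lambda x: x)
    return MetaResult(
        pooled=float(back(mu)), ci_low=float(back(lo)), ci_high=float(back(hi)),
        tau2=tau2, Q=Q, df=df, i2=i_squared(Q, df),
        transform=transform, method=method,
        estimates=est, ses=se_t, pooled_se=se_mu,
        extra={"hartung_knapp": hartung_knapp, "mu_transformed": mu},
    )


def forest_data(meta: MetaResult,
                labels: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Forest-plot table: one row per cluster, a pooled row, heterogeneity.

    Per-cluster CIs are Wald intervals on the analysis scale,
    back-transformed.  The returned frame carries Q, df, tau² and I² in
    ``attrs['heterogeneity']``.
    """
    k = meta.estimates.size
    if labels is None or len(labels) == 0:
        labels = [f"cluster_{i + 1}" for i in range(k)]
    if len(labels) != k:
        raise ValueError(
            f"{len(labels)} labels for {k} estimates"
        )
    back = expit if meta.transform == "logit" else (lambda x: x)
    fwd = logit if meta.transform == "logit" else (lambda x: x)
    theta = fwd(meta.estimates)
    rows = [
        {
            "label": lab,
            "kind": "cluster",
            "estimate": float(meta.estimates[i]),
            "ci_low": float(back(theta[i] - 1.96 * meta.ses[i])),
            "ci_high": float(back(theta[i] + 1.96 * meta.ses[i])),
        }
        for i, lab in enumerate(labels)
    ]
    rows.append({
        "label": "pooled",
        "kind": "pooled",
        "estimate": meta.pooled,
        "ci_low": meta.ci_low,
        "ci_high": meta.ci_high,
    })
    out = pd.DataFrame(rows)
    out.attrs["heterogeneity"] = {
        "Q": meta.Q, "df": meta.df, "tau2": meta.tau2, "i2": meta.i2,
        "method": meta.method, "transform": meta.transform,
    }
    return out
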