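"""Discrimination and calibration metrics for binary risk predictions.

Four measures, mirroring the columns of a standard external-validation
performance table:

* **Harrell's c-statistic** — over all event/non-event pairs, the fraction
  in which the event patient received the higher predicted risk, ties
  counted one half.  Computed by a midrank method (O(n log n)) that equals
  exhaustive pair enumeration exactly; the default standard error is the
  DeLong rank-statistic variance, with a percentile bootstrap as option.
* **Model-based c-statistic** — the concordance expected if outcomes truly
  followed the predicted probabilities.  It depends only on the spread of
  the predictions (the case-mix), not on observed outcomes, so the gap
  between Harrell's c and the model-based c isolates the contribution of
  case-mix homogeneity to an observed drop in discrimination.
* **Calibration intercept** (calibration-in-the-large) — intercept of a
  logistic regression of outcomes on the linear predictor as a fixed
  offset; 0 means agreement on average.
* **Calibration slope** — slope of a logistic regression of outcomes on
  the linear predictor; 1 is ideal, < 1 means predictions too extreme.

Calibration curves (quantile-binned observed vs predicted, plus a lowess
smooth on the logit scale) provide the graphical counterpart.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import expit, logit
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

from .glm import DegenerateOutcomeError, fit_logistic

__all__ = [
    "PerformanceEstimate",
    "CalibrationCurve",
    "harrell_c",
    "model_based_c",
    "calibration_intercept",
    "calibration_slope",
    "calibration_curve",
]

#: above this sample size the model-based c switches to random pairs
MODEL_BASED_C_EXACT_LIMIT = 2000
_N_RANDOM_PAIRS = 1_000_000


@dataclass
class PerformanceEstimate:
    """A named performance metric with uncertainty, tied to one cluster."""

    metric: str
    value: float
    se: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    n: int = 0
    n_events: int = 0
    cluster_id: Optional[str] = None
    note: str = ""

    def as_dict(self) -> dict:
        return {
            "metric": self.metric,
            "cluster": self.cluster_id,
            "value": self.value,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n": self.n,
            "n_events": self.n_events,
            "note": self.note,
        }


@dataclass
class CalibrationCurve:
    """Plottable calibration data: quantile bins plus a smoothed curve."""

    bin_pred_mean: np.ndarray
    bin_obs_frac: np.ndarray
    bin_counts: np.ndarray
    grid_pred: np.ndarray
    grid_smooth: np.ndarray


def _check_binary(y: np.ndarray) -> tuple:
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("y must be binary 0/1")
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise DegenerateOutcomeError(
            "need at least one event and one non-event"
        )
    return y, n1, n0


def harrell_c(p, y, cluster_id: Optional[str] = None,
              ci_method: str = "delong", n_boot: int = 2000,
              seed: int = 0) -> PerformanceEstimate:
    """Harrell's c for binary outcomes, ties in ``p`` counted one half.

    Midrank identity: with R the midranks of ``p`` in the combined sample,
    c = (sum of event midranks - n1(n1+1)/2) / (n1 n0), which equals the
    exhaustive count of concordant pairs plus half the ties.
    """
    p = np.asarray(p, dtype=float)
    y, n1, n0 = _check_binary(y)
    r = rankdata(p)
    c = (r[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    if ci_method == "delong":
        se = _delong_se(p, y)
    elif ci_method == "bootstrap":
        se = _bootstrap_c_se(p, y, n_boot, seed)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    lo = float(np.clip(c - 1.96 * se, 0.0, 1.0))
    hi = float(np.clip(c + 1.96 * se, 0.0, 1.0))
    return PerformanceEstimate("c", float(c), float(se), lo, hi,
                               n=y.size, n_events=n1, cluster_id=cluster_id)


def _delong_se(p: np.ndarray, y: np.ndarray) -> float:
    # Sun & Xu midrank formulation of the DeLong variance
    x, w = p[y == 1], p[y == 0]
    m, n = x.size, w.size
    tz = rankdata(np.concatenate([x, w]))
    tx, tw = rankdata(x), rankdata(w)
    v01 = (tz[:m] - tx) / n           # per-event placement values
    v10 = 1.0 - (tz[m:] - tw) / m     # per-non-event placement values
    s01 = v01.var(ddof=1) if m > 1 else 0.0
    s10 = v10.var(ddof=1) if n > 1 else 0.0
    return float(np.sqrt(s01 / m + s10 / n))


def _bootstrap_c_se(p: np.ndarray, y: np.ndarray, n_boot: int,
                    seed: int) -> float:
    rng = np.random.default_rng(seed)
    n = y.size
    vals = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if yb.min() == yb.max():
            continue
        r = rankdata(p[idx])
        n1 = int(yb.sum())
        vals.append((r[yb == 1].sum() - n1 * (n1 + 1) / 2.0)
                    / (n1 * (n - n1)))
    return float(np.std(vals, ddof=1))


def model_based_c(p, cluster_id: Optional[str] = None,
                  seed: int = 0) -> PerformanceEstimate:
    """Expected concordance were outcomes drawn Bernoulli(p).

    For each pair, the probability-weighted concordant fraction is
    p_max(1-p_min) over a denominator p_i(1-p_j) + p_j(1-p_i); a tied pair
    (p_i = p_j = q) contributes q(1-q) over 2q(1-q), i.e. one half.  Exact
    over all pairs up to n = 2000; beyond that a seeded random-pair
    approximation (10^6 pairs) is used and flagged in ``note``.
    """
    p = np.asarray(p, dtype=float)
    if p.size < 2:
        raise ValueError("model-based c needs at least two predictions")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    note = ""
    if p.size <= MODEL_BASED_C_EXACT_LIMIT:
        pm = np.minimum.outer(p, p)
        pM = np.maximum.outer(p, p)
        iu = np.triu_indices(p.size, k=1)
        num = (pM * (1.0 - pm))[iu].sum()
        den = (np.outer(p, 1.0 - p) + np.outer(1.0 - p, p))[iu].sum()
    else:
        rng = np.random.default_rng(seed)
        i = rng.integers(0, p.size, _N_RANDOM_PAIRS)
        j = rng.integers(0, p.size - 1, _N_RANDOM_PAIRS)
        j[j >= i] += 1  # uniform over ordered pairs with i != j
        pi, pj = p[i], p[j]
        num = (np.maximum(pi, pj) * (1.0 - np.minimum(pi, pj))).sum()
        den = (pi * (1.0 - pj) + pj * (1.0 - pi)).sum()
        note = f"approximate: {_N_RANDOM_PAIRS} random pairs, seed {seed}"
    if den == 0:
        raise ZeroDivisionError(
            "model-based c undefined: all prediction pairs are "
            "deterministic and identical"
        )
    return PerformanceEstimate("c_model_based", float(num / den),
                               n=p.size, cluster_id=cluster_id, note=note)


def calibration_intercept(lp, y, cluster_id: Optional[str] = None
                          ) -> PerformanceEstimate:
    """Calibration-in-the-large: intercept of y ~ offset(lp)."""
    lp = np.asarray(lp, dtype=float)
    y, n1, _ = _check_binary(y)
    fit = fit_logistic(None, y, offset=lp)
    a = fit.intercept
    se = float(np.sqrt(fit.cov[0, 0]))
    return PerformanceEstimate("cal_intercept", a, se,
                               a - 1.96 * se, a + 1.96 * se,
                               n=y.size, n_events=n1, cluster_id=cluster_id)


def calibration_slope(lp, y, cluster_id: Optional[str] = None
                      ) -> PerformanceEstimate:
    """Slope b of the logistic recalibration y ~ a + b*lp."""
    lp = np.asarray(lp, dtype=float)
    y, n1, _ = _check_binary(y)
    if np.ptp(lp) == 0:
        raise ValueError("calibration slope undefined for constant lp")
    fit = fit_logistic(lp[:, None], y)
    b = float(fit.beta[0])
    se = float(np.sqrt(fit.cov[1, 1]))
    return PerformanceEstimate("cal_slope", b, se,
                               b - 1.96 * se, b + 1.96 * se,
                               n=y.size, n_events=n1, cluster_id=cluster_id)


def calibration_curve(p, y, n_bins: int = 10,
                      n_grid: int = 100) -> CalibrationCurve:
    """Quantile-binned observed vs predicted plus a lowess smooth.

    Bins are equal-count quantile bins of ``p`` (collapsed when the
    prediction spread is degenerate).  The smooth is lowess of ``y`` on
    logit(p), with p clipped to [0.001, 0.999] at the boundary.
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    if p.size < n_bins:
        raise ValueError("fewer observations than bins")
    edges = np.unique(np.quantile(p, np.linspace(0, 1, n_bins + 1)))
    if edges.size < 2:  # constant predictions: a single bin
        bin_pred = np.array([p.mean()])
        bin_obs = np.array([y.mean()])
        counts = np.array([p.size])
    else:
        idx = np.clip(np.searchsorted(edges, p, side="right") - 1,
                      0, edges.size - 2)
        ks = np.arange(edges.size - 1)
        counts = np.array([(idx == k).sum() for k in ks])
        keep = counts > 0
        bin_pred = np.array([p[idx == k].mean() for k in ks[keep]])
        bin_obs = np.array([y[idx == k].mean() for k in ks[keep]])
        counts = counts[keep]
    lo = logit(np.clip(p, 1e-3, 1 - 1e-3))
    grid_lo = np.linspace(lo.min(), lo.max(), n_grid)
    sm_pairs = lowess(y, lo, frac=2.0 / 3.0, xvals=grid_lo)
    return CalibrationCurve(
        bin_pred_mean=bin_pred,
        bin_obs_frac=bin_obs,
        bin_counts=counts,
        grid_pred=expit(grid_lo),
        grid_smooth=np.clip(np.asarray(sm_pairs, dtype=float), 0.0, 1.0),
    )
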