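"""Validation engine: apparent, optimism-corrected, and cluster-wise
external validation.

The central procedure is leave-one-cluster-out internal-external
cross-validation: each cluster (study) is held out in turn, the model is
refitted on the remaining clusters, and all performance metrics are
evaluated on the held-out cluster as if it were a predefined external
validation cohort.  The split is non-random — it deliberately exploits
the existing between-study structure.  Per-cluster estimates are then
meta-analyzed (see :mod:`iecv.meta`) and compared against an
optimism-corrected apparent benchmark (Harrell's bootstrap).

When the data were multiply imputed, the whole cross-validation is run
per completed dataset and per-cluster estimates are combined with Rubin's
rules before pooling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .dataset import ClusteredDataset
from .glm import (DegenerateOutcomeError, FittedModel, ModelSpec,
                  SeparationError, fit_model)
from .impute import ImputationSet, rubin_pool
from .metrics import (PerformanceEstimate, calibration_curve,
                      calibration_intercept, calibration_slope, harrell_c,
                      model_based_c)

__all__ = ["ValidationResult", "loco_cv", "loco_cv_mi",
           "optimism_corrected_c", "single_study_view"]

log = logging.getLogger("iecv")

METRICS = ("c", "c_model_based", "cal_intercept", "cal_slope")

#: |Harrell c - model-based c| beyond this is read as a case-mix effect
CASE_MIX_DELTA = 0.02
#: |slope - 1| or |intercept| beyond this is read as miscalibration
MISCAL_BAND = 0.2


@dataclass
class ValidationResult:
    """Tidy per-cluster estimates plus the fitted models and benchmarks."""

    per_cluster: pd.DataFrame          # metric, cluster, value, se, ci, ...
    models: dict                       # cluster -> FittedModel (left-out fit)
    apparent: Optional[PerformanceEstimate] = None
    optimism_corrected: Optional[PerformanceEstimate] = None
    curves: dict = field(default_factory=dict)   # cluster -> CalibrationCurve
    provenance: dict = field(default_factory=dict)

    def estimates(self, metric: str) -> pd.DataFrame:
        sub = self.per_cluster[self.per_cluster["metric"] == metric]
        return sub.set_index("cluster")

    def to_csv(self, path) -> None:
        self.per_cluster.to_csv(path, index=False)


def _evaluate_cluster(model: FittedModel, held: pd.DataFrame,
                      cluster_id: str, with_curve: bool):
    rows, curve = [], None
    lp = model.lp_df(held)
    p = 1.0 / (1.0 + np.exp(-np.clip(lp, -700, 700)))
    y = held["y_favorable"].to_numpy(dtype=float)
    try:
        rows.append(harrell_c(p, y, cluster_id=cluster_id))
        rows.append(model_based_c(p, cluster_id=cluster_id))
        rows.append(calibration_intercept(lp, y, cluster_id=cluster_id))
        rows.append(calibration_slope(lp, y, cluster_id=cluster_id))
        if with_curve and y.size >= 10:
            curve = calibration_curve(p, y)
    except DegenerateOutcomeError:
        warnings.warn(
            f"cluster {cluster_id!r} has a degenerate outcome; "
            f"its metrics are undefined", stacklevel=3)
        rows = [PerformanceEstimate(mname, float("nan"),
                                    cluster_id=cluster_id,
                                    n=y.size, n_events=int(y.sum()),
                                    note="undefined: degenerate outcome")
                for mname in METRICS]
    return rows, curve


def loco_cv(data: ClusteredDataset, spec: Optional[ModelSpec] = None,
            with_curves: bool = True,
            with_apparent: bool = True) -> ValidationResult:
    """Leave-one-cluster-out internal-external cross-validation.

    For each cluster k the model is fitted on all clusters != k and the
    four performance metrics are evaluated on cluster k.  Requires at
    least two clusters and complete predictor data (impute upstream).
    Results are independent of cluster iteration order; clusters are
    processed in first-appearance order.
    """
    spec = spec or ModelSpec()
    clusters = data.clusters
    if len(clusters) < 2:
        raise ValueError("cross-validation requires at least two clusters")
    rows, models, curves = [], {}, {}
    for cid in clusters:
        held, rest = data.split_cluster(cid)
        model = fit_model(rest.df, spec)
        models[cid] = model
        ests, curve = _evaluate_cluster(model, held.df, cid, with_curves)
        rows.extend(ests)
        if curve is not None:
            curves[cid] = curve
        log.info("loco_cv: cluster=%s n_val=%d", cid, held.n)
    apparent = None
    if with_apparent:
        full = fit_model(data.df, spec)
        p = full.predict_df(data.df)
        apparent = harrell_c(p, data.df["y_favorable"].to_numpy())
        apparent.cluster_id = "apparent"
    tidy = pd.DataFrame([e.as_dict() for e in rows])
    return ValidationResult(per_cluster=tidy, models=models,
                            apparent=apparent, curves=curves,
                            provenance={"n": data.n,
                                        "clusters": list(clusters)})


def loco_cv_mi(imputations: ImputationSet,
               spec: Optional[ModelSpec] = None,
               with_curves: bool = True) -> ValidationResult:
    """Cross-validation over an imputation set, Rubin-pooled per cluster.

    Each completed dataset is cross-validated separately; per-cluster,
    per-metric estimates are then combined with Rubin's rules (logit scale
    for concordance statistics).  Calibration curves are taken from the
    first completed dataset.
    """
    results = [loco_cv(d, spec, with_curves=(i == 0 and with_curves),
                       with_apparent=(i == 0))
               for i, d in enumerate(imputations.datasets)]
    frames = pd.concat([r.per_cluster.assign(_imp=i)
                        for i, r in enumerate(results)], ignore_index=True)
    rows = []
    for (metric, cluster), grp in frames.groupby(["metric", "cluster"],
                                                 sort=False):
        vals = grp["value"].to_numpy(dtype=float)
        ses = grp["se"].to_numpy(dtype=float)
        if np.isnan(vals).any():
            rows.append({"metric": metric, "cluster": cluster,
                         "value": float("nan"), "se": float("nan"),
                         "ci_low": float("nan"), "ci_high": float("nan"),
                         "n": int(grp["n"].iloc[0]),
                         "n_events": int(grp["n_events"].iloc[0]),
                         "note": "undefined in >=1 imputation"})
            continue
        if np.isnan(ses).any():  # model-based c carries no SE
            rows.append({"metric": metric, "cluster": cluster,
                         "value": float(vals.mean()), "se": None,
                         "ci_low": None, "ci_high": None,
                         "n": int(grp["n"].iloc[0]),
                         "n_events": int(grp["n_events"].iloc[0]),
                         "note": grp["note"].iloc[0]})
            continue
        transform = "logit" if metric == "c" else "identity"
        pooled = rubin_pool(vals, ses ** 2, transform=transform)
        if transform == "logit":
            from scipy.special import expit as _e, logit as _l
            mu = _l(pooled.pooled)
            lo, hi = _e(mu - 1.96 * pooled.se), _e(mu + 1.96 * pooled.se)
            se_nat = pooled.se * pooled.pooled * (1 - pooled.pooled)
        else:
            lo, hi = (pooled.pooled - 1.96 * pooled.se,
                      pooled.pooled + 1.96 * pooled.se)
            se_nat = pooled.se
        rows.append({"metric": metric, "cluster": cluster,
                     "value": pooled.pooled, "se": se_nat,
                     "ci_low": float(lo), "ci_high": float(hi),
                     "n": int(grp["n"].iloc[0]),
                     "n_events": int(grp["n_events"].iloc[0]),
                     "note": f"rubin m={pooled.m}"})
    first = results[0]
    return ValidationResult(
        per_cluster=pd.DataFrame(rows), models=first.models,
        apparent=first.apparent, curves=first.curves,
        provenance={"m": imputations.m, "seed": imputations.seed,
                    "imputed_variables": imputations.variables})


def optimism_corrected_c(data: ClusteredDataset,
                         spec: Optional[ModelSpec] = None, B: int = 200,
                         seed: int = 0,
                         max_redraws: int = 20) -> PerformanceEstimate:
    """Harrell's bootstrap optimism correction of the apparent c-statistic.

    For each of B resamples (patients drawn with replacement): refit, take
    c on the bootstrap sample minus c of the bootstrap model on the
    original data; the mean of those gaps is the optimism subtracted from
    the apparent c.  B = 0 returns the apparent estimate unchanged.
    """
    spec = spec or ModelSpec()
    full = fit_model(data.df, spec)
    y = data.df["y_favorable"].to_numpy(dtype=float)
    p_app = full.predict_df(data.df)
    apparent = harrell_c(p_app, y)
    if B == 0:
        apparent.note = "B=0: no optimism correction"
        return apparent
    rng = np.random.default_rng(seed)
    n = data.n
    optimism = []
    for _ in range(B):
        bmodel = None
        for attempt in range(max_redraws):
            idx = rng.integers(0, n, n)
            boot = data.df.iloc[idx]
            yb = boot["y_favorable"].to_numpy(dtype=float)
            if not 0.0 < yb.mean() < 1.0:
                continue
            try:  # separated resamples are redrawn like degenerate ones
                bmodel = fit_model(boot, spec)
            except SeparationError:
                continue
            break
        if bmodel is None:
            raise DegenerateOutcomeError(
                f"could not draw a fittable two-class bootstrap sample "
                f"in {max_redraws} attempts")
        c_boot = harrell_c(bmodel.predict_df(boot), yb).value
        c_orig = harrell_c(bmodel.predict_df(data.df), y).value
        optimism.append(c_boot - c_orig)
    opt = float(np.mean(optimism))
    corrected = PerformanceEstimate(
        "c", apparent.value - opt, apparent.se,
        (apparent.ci_low or 0) - opt, (apparent.ci_high or 1) - opt,
        n=n, n_events=int(y.sum()), cluster_id="optimism_corrected",
        note=f"B={B}, optimism={opt:.4f}, seed={seed}")
    return corrected


def single_study_view(result: ValidationResult, cluster_id: str) -> dict:
    """One cluster's estimates framed as a single external validation.

    Includes the case-mix decomposition delta = Harrell's c minus the
    model-based c: a negative delta beyond 0.02 marks a drop in
    discrimination explained by a homogeneous case-mix rather than a bad
    model, while adequate delta with a slope far from 1 (or intercept far
    from 0) points at miscalibration instead.
    """
    sub = result.per_cluster[result.per_cluster["cluster"] == cluster_id]
    if len(sub) == 0:
        raise KeyError(f"unknown cluster {cluster_id!r}")
    vals = {r["metric"]: r for _, r in sub.iterrows()}
    c = vals["c"]["value"]
    cmb = vals["c_model_based"]["value"]
    delta = c - cmb
    if delta < -CASE_MIX_DELTA:
        casemix = "case-mix-driven decrease"
    elif delta > CASE_MIX_DELTA:
        casemix = "case-mix-driven increase"
    else:
        casemix = "no case-mix contribution"
    slope = vals["cal_slope"]["value"]
    intercept = vals["cal_intercept"]["value"]
    miscal = (abs(slope - 1.0) > MISCAL_BAND
              or abs(intercept) > MISCAL_BAND)
    return {
        "cluster": cluster_id,
        "c": c,
        "c_ci": (vals["c"]["ci_low"], vals["c"]["ci_high"]),
        "c_model_based": cmb,
        "delta_case_mix": delta,
        "cal_intercept": intercept,
        "cal_slope": slope,
        "case_mix_label": casemix,
        "calibration_label": ("miscalibration-consistent" if miscal
                              else "calibration adequate"),
        "n": int(vals["c"]["n"]),
        "n_events": int(vals["c"]["n_events"]),
    }
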