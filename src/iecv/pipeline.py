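"""End-to-end pipeline: impute, cross-validate, pool, assess membership.

``run_pipeline`` chains the stages in the order the analysis runs —
load/generate -> impute -> leave-one-cluster-out cross-validation (plus
the optimism-corrected benchmark) -> random-effects pooling ->
membership models -> reports — and writes, under the output directory:

* ``performance_by_cluster.csv``  tidy per-cluster estimates
* ``performance_pooled.csv``      pooled rows with tau², Q and I² per metric
* ``performance_table.csv``       wide, one cluster per row + pooled/range
                                  footer (external-validation table layout)
* ``membership.csv``              membership c + labels per cluster
* ``calibration_<cluster>.csv``   binned + smoothed calibration data
* ``calibration_plots.png``       one panel per cluster
* ``provenance.json``             seeds, sizes, options, package version

Every number in the wide table is copied from the tidy CSVs; nothing is
recomputed at render time.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .dataset import ClusteredDataset, read_dataset
from .glm import ModelSpec
from .impute import mice_fit
from .membership import membership_loco, transportability_report
from .meta import pool
from .synthetic import generate_dataset, sahit_like_preset
from .validation import (ValidationResult, loco_cv, loco_cv_mi,
                         optimism_corrected_c)

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("iecv")

_POOL_TRANSFORM = {"c": "logit", "c_model_based": "logit",
                   "cal_intercept": "identity", "cal_slope": "identity"}


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; every random stage has its own seed."""

    data_path: Optional[str] = None     # CSV input ...
    preset: Optional[str] = None        # ... or generator preset name
    out_dir: str = "results"
    mode: str = "loco"                  # 'loco' or 'external'
    model_spec_path: Optional[str] = None   # required in 'external' mode
    external_cluster: Optional[str] = None
    seed: int = 0
    size_scale: float = 1.0
    m_imputations: int = 5
    mice_iterations: int = 10
    meta_method: str = "REML"
    optimism_B: int = 200
    make_plots: bool = True

    def validate(self) -> None:
        if (self.data_path is None) == (self.preset is None):
            raise ValueError(
                "exactly one of data_path / preset must be given")
        if self.mode not in ("loco", "external"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "external" and self.model_spec_path is None:
            raise ValueError("'external' mode requires model_spec_path")
        if self.preset is not None and self.preset not in ("sahit-like",):
            raise ValueError(f"unknown preset {self.preset!r}")


def _load(config: PipelineConfig) -> ClusteredDataset:
    if config.preset is not None:
        gen = sahit_like_preset(seed=config.seed,
                                size_scale=config.size_scale)
        return generate_dataset(gen)
    return read_dataset(config.data_path)


def _pool_metrics(result: ValidationResult, method: str) -> pd.DataFrame:
    rows = []
    for metric, transform in _POOL_TRANSFORM.items():
        sub = result.per_cluster[result.per_cluster["metric"] == metric]
        sub = sub.dropna(subset=["value", "se"])
        if len(sub) < 2:
            continue
        est = sub["value"].to_numpy(dtype=float)
        if transform == "logit":
            eps = 1e-6
            est = np.clip(est, eps, 1 - eps)
        meta = pool(est, sub["se"].to_numpy(dtype=float),
                    transform=transform, method=method)
        rows.append({
            "metric": metric, "pooled": meta.pooled,
            "ci_low": meta.ci_low, "ci_high": meta.ci_high,
            "tau2": meta.tau2, "Q": meta.Q, "df": meta.df, "i2": meta.i2,
            "transform": transform, "method": method,
            "range_low": float(sub["value"].min()),
            "range_high": float(sub["value"].max()),
            "k": len(sub),
        })
    return pd.DataFrame(rows)


def _wide_table(result: ValidationResult,
                pooled: pd.DataFrame) -> pd.DataFrame:
    wide = result.per_cluster.pivot(index="cluster", columns="metric",
                                    values="value")
    lo = result.per_cluster.pivot(index="cluster", columns="metric",
                                  values="ci_low")
    hi = result.per_cluster.pivot(index="cluster", columns="metric",
                                  values="ci_high")
    out = pd.DataFrame(index=wide.index)
    for metric in _POOL_TRANSFORM:
        if metric not in wide.columns:
            continue
        out[metric] = wide[metric]
        if metric != "c_model_based":
            out[f"{metric}_lo"] = lo[metric]
            out[f"{metric}_hi"] = hi[metric]
    footer = {}
    for _, row in pooled.iterrows():
        m = row["metric"]
        footer[m] = row["pooled"]
        if m != "c_model_based":
            footer[f"{m}_lo"] = row["ci_low"]
            footer[f"{m}_hi"] = row["ci_high"]
    out.loc["pooled (RE meta-analysis)"] = pd.Series(footer)
    i2_row = {row["metric"]: row["i2"] for _, row in pooled.iterrows()}
    out.loc["I2 (%)"] = pd.Series(i2_row)
    return out.reset_index(names="cluster")


def _plot_calibration(result: ValidationResult, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    curves = result.curves
    if not curves:
        return
    k = len(curves)
    ncol = min(4, k)
    nrow = int(np.ceil(k / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 3.0 * nrow),
                             squeeze=False)
    for ax, (cid, curve) in zip(axes.flat, curves.items()):
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.plot(curve.grid_pred, curve.grid_smooth, "-", color="C0")
        ax.plot(curve.bin_pred_mean, curve.bin_obs_frac, "o", ms=3,
                color="C1")
        ax.set_title(str(cid), fontsize=9)
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1)
    for ax in axes.flat[k:]:
        ax.axis("off")
    fig.supxlabel("predicted probability")
    fig.supylabel("observed fraction")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full validation pipeline; returns paths and results."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    data = _load(config)
    log.info("stage=load n=%d clusters=%d seed=%d elapsed=%.1fs",
             data.n, len(data.clusters), config.seed, time.time() - t0)

    has_missing = data.df[
        ["age", "wfns_high", "hypertension", "fisher", "size_large",
         "location"]].isna().any().any()
    if has_missing:
        imps = mice_fit(data, m=config.m_imputations,
                        iterations=config.mice_iterations,
                        seed=config.seed + 1)
        log.info("stage=impute m=%d vars=%s elapsed=%.1fs",
                 imps.m, imps.variables, time.time() - t0)
        result = loco_cv_mi(imps, with_curves=config.make_plots)
        eval_data = imps.datasets[0]
    else:
        imps = None
        result = loco_cv(data, with_curves=config.make_plots)
        eval_data = data
    log.info("stage=loco_cv clusters=%d elapsed=%.1fs",
             len(result.models), time.time() - t0)

    result.optimism_corrected = optimism_corrected_c(
        eval_data, B=config.optimism_B, seed=config.seed + 2)
    log.info("stage=optimism B=%d corrected=%.3f elapsed=%.1fs",
             config.optimism_B, result.optimism_corrected.value,
             time.time() - t0)

    pooled = _pool_metrics(result, config.meta_method)
    log.info("stage=meta_pool metrics=%d elapsed=%.1fs",
             len(pooled), time.time() - t0)

    c_by_cluster = result.estimates("c")["value"].to_dict()
    memb = membership_loco(eval_data, c_validation=c_by_cluster)
    memb_table = transportability_report(memb)
    log.info("stage=membership clusters=%d elapsed=%.1fs",
             len(memb), time.time() - t0)

    # -- reports ----------------------------------------------------------
    paths = {}
    result.per_cluster.to_csv(out_dir / "performance_by_cluster.csv",
                              index=False)
    paths["per_cluster"] = out_dir / "performance_by_cluster.csv"
    pooled.to_csv(out_dir / "performance_pooled.csv", index=False)
    paths["pooled"] = out_dir / "performance_pooled.csv"
    wide = _wide_table(result, pooled)
    wide.to_csv(out_dir / "performance_table.csv", index=False)
    paths["table"] = out_dir / "performance_table.csv"
    memb_table.to_csv(out_dir / "membership.csv", index=False)
    paths["membership"] = out_dir / "membership.csv"
    for cid, curve in result.curves.items():
        safe = str(cid).replace("/", "-")
        pd.DataFrame({"bin_pred": curve.bin_pred_mean,
                      "bin_obs": curve.bin_obs_frac,
                      "bin_n": curve.bin_counts}).to_csv(
            out_dir / f"calibration_{safe}.csv", index=False)
    if config.make_plots:
        _plot_calibration(result, out_dir / "calibration_plots.png")
        paths["plots"] = out_dir / "calibration_plots.png"
    prov = {
        "version": __version__,
        "seed": config.seed,
        "n": data.n,
        "clusters": [str(c) for c in data.clusters],
        "mode": config.mode,
        "preset": config.preset,
        "size_scale": config.size_scale,
        "imputation": ({"m": imps.m, "iterations": imps.iterations,
                        "seed": imps.seed,
                        "variables": imps.variables,
                        "methods": imps.methods} if imps else None),
        "meta_method": config.meta_method,
        "optimism_B": config.optimism_B,
        "scale_priority": ["GOS", "mRS", "eGOS"],
        "elapsed_s": round(time.time() - t0, 2),
    }
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(prov, fh, indent=2)
    paths["provenance"] = out_dir / "provenance.json"
    return {"paths": paths, "result": result, "pooled": pooled,
            "membership": memb_table, "data": data,
            "optimism_corrected": result.optimism_corrected}
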