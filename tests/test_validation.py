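"""Validation engine: cross-validation against a hand-scripted oracle,
optimism bootstrap, single-study reports."""

import numpy as np
import pytest

from conftest import make_config, make_spec
from iecv.glm import ModelSpec, fit_model
from iecv.impute import mice_fit
from iecv.metrics import (calibration_intercept, calibration_slope,
                          harrell_c, model_based_c)
from iecv.synthetic import generate_dataset
from iecv.validation import (loco_cv, loco_cv_mi, optimism_corrected_c,
                             single_study_view)


def test_loco_cv_equals_hand_scripted_fits(three_cluster_data):
    """Engine output == direct fit-then-evaluate loop, cluster by cluster."""
    result = loco_cv(three_cluster_data, with_curves=False)
    for cid in three_cluster_data.clusters:
        held, rest = three_cluster_data.split_cluster(cid)
        model = fit_model(rest.df)        # oracle: two-step script
        lp = model.lp_df(held.df)
        p = 1 / (1 + np.exp(-lp))
        y = held.df["y_favorable"].to_numpy()
        expect = {
            "c": harrell_c(p, y).value,
            "c_model_based": model_based_c(p).value,
            "cal_intercept": calibration_intercept(lp, y).value,
            "cal_slope": calibration_slope(lp, y).value,
        }
        got = result.estimates("c").loc[cid, "value"]
        assert got == pytest.approx(expect["c"], abs=1e-10)
        for metric, val in expect.items():
            got = result.per_cluster[
                (result.per_cluster["metric"] == metric)
                & (result.per_cluster["cluster"] == cid)]["value"].iloc[0]
            assert got == pytest.approx(val, abs=1e-8)


def test_loco_cv_row_counts_and_models(three_cluster_data):
    result = loco_cv(three_cluster_data, with_curves=False)
    counts = result.per_cluster.groupby("metric")["cluster"].count()
    assert (counts == 3).all()
    assert set(result.models) == set(three_cluster_data.clusters)


def test_loco_cv_order_invariance(three_cluster_data):
    """Re-ordering clusters in the input changes nothing per cluster."""
    result = loco_cv(three_cluster_data, with_curves=False,
                     with_apparent=False)
    shuffled = three_cluster_data.copy()
    shuffled.df = shuffled.df.sort_values(
        "cluster", ascending=False, kind="stable").reset_index(drop=True)
    result2 = loco_cv(shuffled, with_curves=False, with_apparent=False)
    a = result.per_cluster.set_index(["metric", "cluster"])["value"]
    b = result2.per_cluster.set_index(["metric", "cluster"])["value"]
    for key in a.index:
        assert a[key] == pytest.approx(b[key], abs=1e-10)


def test_loco_cv_single_cluster_errors():
    data = generate_dataset(make_config([make_spec("only", 200)], seed=1))
    with pytest.raises(ValueError, match="two clusters"):
        loco_cv(data)


def test_loco_cv_degenerate_cluster_flagged():
    specs = [make_spec("ok1", 300), make_spec("ok2", 300),
             make_spec("allfav", 60, intercept_shift=30.0)]
    data = generate_dataset(make_config(specs, seed=2))
    assert data.df[data.df.cluster == "allfav"]["y_favorable"].min() == 1.0
    with pytest.warns(UserWarning, match="degenerate"):
        result = loco_cv(data, with_curves=False)
    sub = result.per_cluster[result.per_cluster["cluster"] == "allfav"]
    assert sub["value"].isna().all()
    assert (sub["note"].str.contains("undefined")).all()


def test_exchangeable_clusters_reproduce_apparent_performance(
        exchangeable_pair):
    """No heterogeneity: held-out c near apparent c, slopes near 1."""
    result = loco_cv(exchangeable_pair, with_curves=False)
    c_app = result.apparent.value
    for cid in exchangeable_pair.clusters:
        c_est = result.estimates("c").loc[cid]
        assert abs(c_est["value"] - c_app) < 3 * c_est["se"]
        s_est = result.estimates("cal_slope").loc[cid]
        assert abs(s_est["value"] - 1.0) < 3 * s_est["se"]


def test_fourteen_cluster_preset_yields_14_rows_per_metric():
    from iecv.synthetic import sahit_like_preset
    cfg = sahit_like_preset(seed=3, size_scale=0.1)
    data = generate_dataset(cfg)
    imps = mice_fit(data, m=2, iterations=3, seed=4)
    result = loco_cv_mi(imps, with_curves=False)
    counts = result.per_cluster.groupby("metric")["cluster"].count()
    assert (counts == 14).all()
    assert (result.per_cluster["note"].str.startswith("rubin")
            | result.per_cluster["se"].isna()).all()


# -- optimism bootstrap ---------------------------------------------------

def test_optimism_b0_returns_apparent(three_cluster_data):
    est = optimism_corrected_c(three_cluster_data, B=0)
    full = fit_model(three_cluster_data.df)
    apparent = harrell_c(full.predict_df(three_cluster_data.df),
                         three_cluster_data.df["y_favorable"].to_numpy())
    assert est.value == pytest.approx(apparent.value, abs=1e-12)


def test_optimism_large_n_is_small():
    """With n >> p the expected optimism is negligible."""
    data = generate_dataset(make_config([make_spec("big", 20_000)], seed=5))
    full = fit_model(data.df)
    apparent = harrell_c(full.predict_df(data.df),
                         data.df["y_favorable"].to_numpy()).value
    est = optimism_corrected_c(data, B=40, seed=6)
    assert apparent - est.value < 0.005


def test_optimism_corrects_downward_in_overfit_setting():
    data = generate_dataset(make_config([make_spec("tiny", 100)], seed=7))
    full = fit_model(data.df)
    apparent = harrell_c(full.predict_df(data.df),
                         data.df["y_favorable"].to_numpy()).value
    est = optimism_corrected_c(data, B=100, seed=8)
    assert est.value < apparent


# -- single-study view ----------------------------------------------------

def _fake_result(c, cmb, intercept, slope):
    import pandas as pd

    from iecv.validation import ValidationResult
    rows = [
        {"metric": "c", "cluster": "X", "value": c, "se": 0.02,
         "ci_low": c - 0.04, "ci_high": c + 0.04, "n": 500, "n_events": 400,
         "note": ""},
        {"metric": "c_model_based", "cluster": "X", "value": cmb,
         "se": None, "ci_low": None, "ci_high": None, "n": 500,
         "n_events": 400, "note": ""},
        {"metric": "cal_intercept", "cluster": "X", "value": intercept,
         "se": 0.1, "ci_low": intercept - 0.2, "ci_high": intercept + 0.2,
         "n": 500, "n_events": 400, "note": ""},
        {"metric": "cal_slope", "cluster": "X", "value": slope, "se": 0.1,
         "ci_low": slope - 0.2, "ci_high": slope + 0.2, "n": 500,
         "n_events": 400, "note": ""},
    ]
    return ValidationResult(per_cluster=pd.DataFrame(rows), models={})


def test_single_study_view_case_mix_decrease():
    report = single_study_view(_fake_result(0.66, 0.76, 0.0, 1.0), "X")
    assert report["delta_case_mix"] == pytest.approx(-0.10)
    assert report["case_mix_label"] == "case-mix-driven decrease"
    assert report["calibration_label"] == "calibration adequate"


def test_single_study_view_no_case_mix_contribution():
    report = single_study_view(_fake_result(0.75, 0.75, 0.0, 1.0), "X")
    assert report["delta_case_mix"] == 0.0
    assert report["case_mix_label"] == "no case-mix contribution"


def test_single_study_view_miscalibration_flag():
    report = single_study_view(_fake_result(0.75, 0.71, -1.4, 1.17), "X")
    assert report["case_mix_label"] == "case-mix-driven increase"
    assert report["calibration_label"] == "miscalibration-consistent"


def test_single_study_view_unknown_cluster():
    with pytest.raises(KeyError):
        single_study_view(_fake_result(0.7, 0.7, 0.0, 1.0), "nope")
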