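"""Published per-cluster validation results for the SAHIT outcome model.

The original leave-one-cluster-out validation of the refitted SAHIT model
(14 studies, n = 11,931) reported per-cluster discrimination and
calibration together with random-effects pooled summaries.  The underlying
patient data are restricted, but the pooled rows are pure functions of the
printed per-cluster rows, so they can be re-derived from the numbers below:
feed the per-cluster estimates and 95% CIs to :func:`iecv.meta.pool` (logit
scale for the c-statistic, identity scale for intercept and slope, standard
errors reconstructed as CI width / 3.92 on the analysis scale).

``PERFORMANCE`` holds, per cluster: Harrell's c with 95% CI, the
model-based c, the calibration intercept with CI and the calibration slope
with CI.  ``MEMBERSHIP_C`` holds the membership-model c-statistics used for
the transportability readout.  The reported optimism-corrected apparent
c-statistic (200 bootstrap samples) was 0.77 (0.76-0.78).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["PERFORMANCE", "MEMBERSHIP_C", "performance_frame",
           "membership_frame", "OPTIMISM_CORRECTED_C"]

OPTIMISM_CORRECTED_C = {"value": 0.77, "ci_low": 0.76, "ci_high": 0.78}

# cluster: (c, c_lo, c_hi, c_model_based,
#           intercept, int_lo, int_hi, slope, slope_lo, slope_hi)
PERFORMANCE = {
    "Conscious-1": (0.78, 0.72, 0.83, 0.76, -0.10, -0.36, 0.15, 1.12, 0.83, 1.38),
    "Chicago":     (0.73, 0.61, 0.84, 0.77,  0.75,  0.23, 1.27, 0.82, 0.31, 1.34),
    "EPO/Statin":  (0.76, 0.68, 0.84, 0.76,  0.55,  0.19, 0.91, 1.02, 0.64, 1.40),
    "HHU":         (0.75, 0.59, 0.91, 0.71, -1.40, -2.08, -0.71, 1.17, 0.16, 2.17),
    "IHAST":       (0.71, 0.66, 0.76, 0.68,  0.02, -0.17, 0.21, 1.21, 0.91, 1.51),
    "IMASH":       (0.52, 0.45, 0.59, 0.78,  0.42,  0.16, 0.67, 0.10, -0.11, 0.30),
    "ISAT":        (0.68, 0.65, 0.71, 0.70, -0.02, -0.15, 0.11, 0.96, 0.80, 1.12),
    "Leeds":       (0.66, 0.52, 0.79, 0.76, -0.02, -0.52, 0.48, 0.53, 0.05, 1.01),
    "MAPS":        (0.81, 0.70, 0.92, 0.74, -0.91, -1.38, -0.44, 1.25, 0.76, 1.73),
    "MASH1/2":     (0.76, 0.73, 0.79, 0.77,  0.25,  0.12, 0.37, 0.99, 0.86, 1.12),
    "D-SAT":       (0.80, 0.75, 0.85, 0.78,  0.21, -0.04, 0.45, 1.24, 0.96, 1.51),
    "SHOP":        (0.84, 0.82, 0.86, 0.80,  0.47,  0.35, 0.59, 1.31, 1.18, 1.45),
    "Tirilazad":   (0.76, 0.74, 0.78, 0.77, -0.38, -0.48, -0.29, 0.91, 0.82, 1.00),
    "Utrecht":     (0.76, 0.68, 0.83, 0.78, -1.03, -1.34, -0.72, 0.89, 0.60, 1.17),
}

#: membership-model c-statistic per left-out cluster
MEMBERSHIP_C = {
    "Conscious-1": 0.80,
    "Chicago": 0.85,
    "EPO/Statin": 0.84,
    "HHU": 0.93,
    "IHAST": 0.76,
    "IMASH": 0.79,
    "ISAT": 0.70,
    "Leeds": 0.69,
    "MAPS": 0.73,
    "MASH1/2": 0.62,
    "D-SAT": 0.73,
    "SHOP": 0.78,
    "Tirilazad": 0.82,
    "Utrecht": 0.74,
}

_COLS = ["c", "c_lo", "c_hi", "c_model_based",
         "intercept", "intercept_lo", "intercept_hi",
         "slope", "slope_lo", "slope_hi"]


def performance_frame() -> pd.DataFrame:
    """Per-cluster published performance as a tidy frame (index: cluster)."""
    return pd.DataFrame.from_dict(PERFORMANCE, orient="index",
                                  columns=_COLS).rename_axis("cluster")


def membership_frame() -> pd.DataFrame:
    """Published membership-model c-statistics (index: cluster)."""
    return pd.DataFrame.from_dict(MEMBERSHIP_C, orient="index",
                                  columns=["c_membership"]
                                  ).rename_axis("cluster")
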