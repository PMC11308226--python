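"""Membership models: relatedness of development and validation samples.

A membership model is a logistic regression that predicts whether a
patient belongs to the development (0) or validation (1) sample, using
all six predictors plus the dichotomized outcome.  Its apparent
c-statistic measures how separable — how *unrelated* — the two samples
are: c near 0.5 means exchangeable samples (performance there speaks to
generalizability), c near 1 means a distinctly different population
(performance there speaks to transportability).

Joint reading with the validation c-statistic:

==================  =======================  ==========================
membership c        validation c >= 0.70     validation c < 0.70
==================  =======================  ==========================
< 0.70 (related)    good generalizability    poor generalizability
0.70-0.80           good transportability    questionable transportability
                    (moderately distinct)    (moderately distinct)
>= 0.80 (distinct)  good transportability    poor transportability
==================  =======================  ==========================
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .dataset import ClusteredDataset
from .glm import ModelSpec, SeparationError, fit_logistic
from .metrics import harrell_c

__all__ = ["MembershipResult", "membership_c", "membership_loco",
           "transportability_report", "RELATEDNESS_BANDS"]

#: relatedness bands on the membership c: related < 0.70 <= moderately
#: distinct < 0.80 <= distinct
RELATEDNESS_BANDS = (0.70, 0.80)

#: validation c at or above this counts as satisfactory discrimination
SATISFACTORY_C = 0.70


@dataclass
class MembershipResult:
    cluster_id: Optional[str]
    c_membership: float
    c_validation: Optional[float] = None
    separation: bool = False
    n_dev: int = 0
    n_val: int = 0

    @property
    def relatedness(self) -> str:
        lo, hi = RELATEDNESS_BANDS
        if self.c_membership < lo:
            return "related"
        if self.c_membership < hi:
            return "moderately distinct"
        return "distinct"

    @property
    def transportability(self) -> str:
        if self.c_validation is None or np.isnan(self.c_validation):
            return "not assessed"
        good = self.c_validation >= SATISFACTORY_C
        if self.relatedness == "related":
            return ("good generalizability" if good
                    else "poor generalizability")
        if self.relatedness == "distinct":
            return ("good transportability" if good
                    else "poor transportability")
        return ("good transportability" if good
                else "questionable transportability")


def membership_c(dev: ClusteredDataset, val: ClusteredDataset,
                 spec: Optional[ModelSpec] = None,
                 c_validation: Optional[float] = None,
                 cluster_id: Optional[str] = None) -> MembershipResult:
    """Apparent c-statistic of the development-vs-validation membership model.

    Complete covariate separation between the samples is not an error —
    it is the "perfectly distinct" extreme and is reported as c = 1.0
    with the ``separation`` flag set.
    """
    if dev.n == 0 or val.n == 0:
        raise ValueError("both samples must be non-empty")
    spec = spec or ModelSpec()
    df = pd.concat([dev.df, val.df], ignore_index=True)
    member = np.concatenate([np.zeros(dev.n), np.ones(val.n)])
    X = spec.design_matrix(df)
    X = np.column_stack([X, df["y_favorable"].to_numpy(dtype=float)])
    try:
        fit = fit_logistic(X, member,
                           column_names=spec.column_names + ["y_favorable"])
        p = fit.predict(X)
        c = harrell_c(p, member).value
        sep = False
    except SeparationError:
        c, sep = 1.0, True
    return MembershipResult(cluster_id=cluster_id, c_membership=float(c),
                            c_validation=c_validation, separation=sep,
                            n_dev=dev.n, n_val=val.n)


def membership_loco(data: ClusteredDataset,
                    spec: Optional[ModelSpec] = None,
                    c_validation: Optional[dict] = None) -> list:
    """Membership model for every leave-one-cluster-out split.

    ``c_validation`` optionally maps cluster id to that cluster's
    validation c-statistic so the joint transportability label can be
    assigned.
    """
    c_validation = c_validation or {}
    out = []
    for cid in data.clusters:
        val, dev = data.split_cluster(cid)
        out.append(membership_c(dev, val, spec,
                                c_validation=c_validation.get(cid),
                                cluster_id=cid))
    return out


def transportability_report(results: list) -> pd.DataFrame:
    """Tidy per-cluster table of membership c, validation c, and labels."""
    if len(results) == 0:
        raise ValueError("need at least one cluster result")
    return pd.DataFrame([
        {
            "cluster": r.cluster_id,
            "c_membership": r.c_membership,
            "c_validation": r.c_validation,
            "relatedness": r.relatedness,
            "transportability": r.transportability,
            "separation": r.separation,
        }
        for r in results
    ])
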