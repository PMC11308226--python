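"""Shared fixtures: compact synthetic study configurations."""

from __future__ import annotations

import numpy as np
import pytest

from iecv.synthetic import ClusterSpec, GeneratorConfig, generate_dataset

#: a simple, plausible coefficient vector on the 12-term encoding
BETA = (-0.04, -1.2, -0.3, -0.2, -0.5, -0.8, -0.4,
        0.1, 0.0, -0.2, 0.1, -0.3)
INTERCEPT = 4.0

POOL_FISHER = (0.05, 0.21, 0.39, 0.35)
POOL_LOC = (0.196, 0.202, 0.197, 0.184, 0.090, 0.131)


def make_spec(cid: str, n: int, **kw) -> ClusterSpec:
    base = dict(
        cluster_id=cid, n=n, age_mean=53.0, age_sd=13.0,
        p_wfns_high=0.2, p_hypertension=0.4,
        fisher_probs=POOL_FISHER, p_size_large=0.16,
        location_probs=POOL_LOC,
    )
    base.update(kw)
    return ClusterSpec(**base)


def make_config(specs, seed=0, **kw) -> GeneratorConfig:
    base = dict(cluster_specs=tuple(specs), true_beta=BETA,
                true_intercept=INTERCEPT, seed=seed)
    base.update(kw)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def three_cluster_data():
    """Three complete clusters with mild intercept heterogeneity."""
    specs = [
        make_spec("A", 300, intercept_shift=0.0),
        make_spec("B", 250, intercept_shift=0.4, p_wfns_high=0.35),
        make_spec("C", 200, intercept_shift=-0.4, age_mean=58.0),
    ]
    return generate_dataset(make_config(specs, seed=7))


@pytest.fixture(scope="session")
def exchangeable_pair():
    """Two identically-specified clusters, no heterogeneity."""
    specs = [make_spec("dev", 2000), make_spec("val", 2000)]
    return generate_dataset(make_config(specs, seed=11))
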