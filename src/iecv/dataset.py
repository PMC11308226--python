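"""Clustered patient dataset container and its CSV interchange format.

A :class:`ClusteredDataset` is a thin wrapper around a pandas DataFrame
with one row per patient and a fixed column vocabulary:

``cluster, age, wfns_high, hypertension, fisher, size_large, location,
outcome_scale, outcome_raw, y_favorable``

plus a metadata dict (block-missingness map, generating configuration,
seeds).  Datasets round-trip as a CSV with a JSON sidecar
(``<name>.csv`` + ``<name>.meta.json``); missing values are empty cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .glm import FISHER_GRADES, LOCATIONS

__all__ = ["ClusteredDataset", "PREDICTOR_COLUMNS", "read_dataset",
           "write_dataset"]

PREDICTOR_COLUMNS = ("age", "wfns_high", "hypertension", "fisher",
                     "size_large", "location")
_ALL_COLUMNS = ("cluster",) + PREDICTOR_COLUMNS + (
    "outcome_scale", "outcome_raw", "y_favorable")


@dataclass
class ClusteredDataset:
    """One row per patient; ``cluster`` labels the source study."""

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in ("cluster", "y_favorable")
                   if c not in self.df.columns]
        if missing:
            raise ValueError(f"dataset lacks required columns {missing}")
        self.df = self.df.reset_index(drop=True)

    # -- cluster access ---------------------------------------------------
    @property
    def clusters(self) -> list:
        return list(pd.unique(self.df["cluster"]))

    @property
    def n(self) -> int:
        return len(self.df)

    def cluster_sizes(self) -> pd.Series:
        return self.df["cluster"].value_counts().reindex(self.clusters)

    def subset(self, clusters: Iterable[str]) -> "ClusteredDataset":
        clusters = list(clusters)
        sub = self.df[self.df["cluster"].isin(clusters)]
        return ClusteredDataset(sub.copy(), dict(self.meta))

    def split_cluster(self, cluster_id: str):
        """Return (held-out cluster, remainder) datasets."""
        if cluster_id not in self.clusters:
            raise KeyError(f"unknown cluster {cluster_id!r}")
        mask = self.df["cluster"] == cluster_id
        return (ClusteredDataset(self.df[mask].copy(), dict(self.meta)),
                ClusteredDataset(self.df[~mask].copy(), dict(self.meta)))

    def copy(self) -> "ClusteredDataset":
        return ClusteredDataset(self.df.copy(), json.loads(json.dumps(
            self.meta, default=_jsonable)))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, set):
        return sorted(obj)
    return str(obj)


def _validate_levels(df: pd.DataFrame) -> None:
    if "location" in df.columns:
        vals = df["location"].dropna()
        bad = vals[~vals.isin(LOCATIONS)]
        if len(bad):
            i = bad.index[0]
            raise ValueError(
                f"row {i}: unknown location level {bad.iloc[0]!r} "
                f"(column 'location')"
            )
    if "fisher" in df.columns:
        vals = df["fisher"].dropna()
        bad = vals[~vals.isin(FISHER_GRADES)]
        if len(bad):
            i = bad.index[0]
            raise ValueError(
                f"row {i}: Fisher grade {bad.iloc[0]!r} outside 1-4 "
                f"(column 'fisher')"
            )


def write_dataset(data: ClusteredDataset, path) -> None:
    """Write a dataset as CSV plus a ``.meta.json`` sidecar."""
    path = Path(path)
    data.df.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + "").parent / (
        path.stem + ".meta.json")
    with open(sidecar, "w") as fh:
        json.dump({"columns": {c: str(data.df[c].dtype)
                               for c in data.df.columns},
                   "meta": data.meta}, fh, indent=2, default=_jsonable)


def read_dataset(path, meta_path: Optional[str] = None) -> ClusteredDataset:
    """Read a dataset CSV (+ optional JSON sidecar), validating the schema.

    Unknown location levels or out-of-range Fisher grades are rejected
    with the offending row named; an empty file (header only) errors.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"cluster": str, "location": str,
                                  "outcome_scale": str})
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    unknown = [c for c in df.columns if c not in _ALL_COLUMNS
               and not c.startswith("_")]
    if unknown:
        raise ValueError(f"{path}: unrecognized columns {unknown}")
    _validate_levels(df)
    if "fisher" in df.columns:
        df["fisher"] = df["fisher"].astype("Int64").astype("float")
    if "y_favorable" not in df.columns:
        if not {"outcome_scale", "outcome_raw"} <= set(df.columns):
            raise ValueError(
                f"{path}: need either a y_favorable column or the pair "
                f"outcome_scale + outcome_raw")
        from .outcomes import favorable_from_scores
        df["y_favorable"] = pd.array(
            favorable_from_scores(df["outcome_scale"], df["outcome_raw"]),
            dtype="float")
    meta: dict = {}
    sidecar = (Path(meta_path) if meta_path
               else path.parent / (path.stem + ".meta.json"))
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh).get("meta", {})
    return ClusteredDataset(df, meta)
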