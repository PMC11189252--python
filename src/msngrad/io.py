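"""Readers and writers for the pipeline's delimited text formats.

Canonical formats (all CSV with headers):

- cohort features: long table with columns subject_id, region, feature, value
- cohort metadata: subject_id, age, sex, site, etiv (+ optional extra
  numeric columns, e.g. behavioral scores)
- partition: region, network (+ optional coord_x, coord_y, coord_z)
- dense matrices (MSN, annotation maps): region-id header row and column
- gradients: region_id, G1..Gk (+ sidecar metadata with eigenvalues)
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import NetworkPartition, SubjectFeatures
from .manifold import GradientSet

__all__ = [
    "save_cohort", "load_cohort",
    "save_partition", "load_partition",
    "save_matrix", "load_matrix",
    "save_gradients", "load_gradients",
]

METADATA_COLUMNS = ["subject_id", "age", "sex", "site", "etiv"]


def region_names(n: int) -> list:
    return [f"r{i:04d}" for i in range(n)]


def feature_names(n: int) -> list:
    # GMV, SA, CT, GC, MC for the 5-feature default; FA, MD extend to 7
    canonical = ["GMV", "SA", "CT", "GC", "MC", "FA", "MD"]
    return canonical[:n] if n <= len(canonical) else [f"f{i}" for i in range(n)]


def save_cohort(cohort, features_path, metadata_path):
    """Write a cohort as a long feature table plus a metadata table."""
    R, F = cohort[0].X.shape
    regions = region_names(R)
    feats = feature_names(F)
    rows = []
    for s in cohort:
        long = pd.DataFrame(s.X, index=regions, columns=feats).stack().reset_index()
        long.columns = ["region", "feature", "value"]
        long.insert(0, "subject_id", s.subject_id)
        rows.append(long)
    pd.concat(rows, ignore_index=True).to_csv(features_path, index=False)
    meta = pd.DataFrame(
        [
            {"subject_id": s.subject_id, "age": s.age, "sex": s.sex,
             "site": s.site, "etiv": s.etiv}
            for s in cohort
        ]
    )
    meta.to_csv(metadata_path, index=False)


def load_cohort(features_path, metadata_path):
    """Read a cohort back; validates completeness and consistency.

    Returns
    -------
    cohort : list of SubjectFeatures
    meta : DataFrame indexed by subject_id (keeps any extra columns, e.g.
        behavioral scores)
    """
    feats = pd.read_csv(features_path)
    missing_cols = {"subject_id", "region", "feature", "value"} - set(feats.columns)
    if missing_cols:
        raise ValueError(f"feature table lacks columns: {sorted(missing_cols)}")
    if not pd.api.types.is_numeric_dtype(feats["value"]):
        bad = feats.loc[pd.to_numeric(feats["value"], errors="coerce").isna()]
        raise ValueError(f"non-numeric feature values, e.g. rows {bad.index[:3].tolist()}")
    dup = feats.duplicated(["subject_id", "region", "feature"])
    if dup.any():
        first = feats.loc[dup.idxmax()]
        raise ValueError(
            "duplicated (subject, region, feature) row: "
            f"{first['subject_id']}/{first['region']}/{first['feature']}"
        )
    meta = pd.read_csv(metadata_path)
    missing_cols = set(METADATA_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise ValueError(f"metadata lacks columns: {sorted(missing_cols)}")
    meta = meta.set_index("subject_id")
    unknown = set(feats["subject_id"]) - set(meta.index)
    if unknown:
        raise ValueError(f"subject(s) in features but not metadata: {sorted(unknown)[:5]}")
    absent = set(meta.index) - set(feats["subject_id"])
    if absent:
        raise ValueError(f"subject(s) in metadata but without features: {sorted(absent)[:5]}")

    # preserve first-appearance order so write -> load round-trips exactly
    regions = list(pd.unique(feats["region"]))
    features = list(pd.unique(feats["feature"]))
    cohort = []
    for sid, grp in feats.groupby("subject_id", sort=True):
        wide = grp.pivot(index="region", columns="feature", values="value")
        if wide.isna().any().any() or wide.shape != (len(regions), len(features)):
            missing = [
                (r, f) for r in regions for f in features
                if r not in wide.index or f not in wide.columns or pd.isna(wide.loc[r, f])
            ]
            raise ValueError(f"subject {sid}: missing region/feature cells, e.g. {missing[:3]}")
        wide = wide.reindex(index=regions, columns=features)
        m = meta.loc[sid]
        cohort.append(
            SubjectFeatures(
                subject_id=str(sid), age=float(m["age"]), sex=str(m["sex"]),
                site=str(m["site"]), etiv=float(m["etiv"]), X=wide.to_numpy(),
            )
        )
    return cohort, meta


def save_partition(partition: NetworkPartition, path):
    df = pd.DataFrame(
        {
            "region": region_names(partition.n_regions),
            "network": [partition.names[b] for b in partition.labels],
        }
    )
    if partition.coords is not None:
        df[["coord_x", "coord_y", "coord_z"]] = partition.coords
    df.to_csv(path, index=False)


def load_partition(path) -> NetworkPartition:
    df = pd.read_csv(path)
    if not {"region", "network"} <= set(df.columns):
        raise ValueError("partition file needs 'region' and 'network' columns")
    df = df.sort_values("region").reset_index(drop=True)
    names = sorted(df["network"].unique().tolist())
    labels = np.array([names.index(v) for v in df["network"]])
    coords = None
    if {"coord_x", "coord_y", "coord_z"} <= set(df.columns):
        coords = df[["coord_x", "coord_y", "coord_z"]].to_numpy(dtype=float)
    return NetworkPartition(labels=labels, names=names, coords=coords)


def save_matrix(values, path, row_ids=None, col_ids=None):
    """Dense delimited matrix with id header row/column."""
    values = np.asarray(values)
    rows = row_ids if row_ids is not None else region_names(values.shape[0])
    cols = col_ids if col_ids is not None else [f"c{i:04d}" for i in range(values.shape[1])]
    pd.DataFrame(values, index=rows, columns=cols).to_csv(path, index_label="id")


def load_matrix(path):
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), df.index.tolist(), df.columns.tolist()


def save_gradients(gs: GradientSet, path, meta_path=None):
    cols = [f"G{i + 1}" for i in range(gs.n_components)]
    df = pd.DataFrame(gs.gradients, columns=cols)
    df.insert(0, "region_id", region_names(gs.n_regions))
    df.to_csv(path, index=False)
    if meta_path is not None:
        Path(meta_path).write_text(
            json.dumps({"eigenvalues": gs.eigenvalues.tolist(), "params": gs.params}, indent=2)
        )


def load_gradients(path, meta_path=None) -> GradientSet:
    df = pd.read_csv(path)
    G = df[[c for c in df.columns if c.startswith("G")]].to_numpy(dtype=float)
    eig, params = np.array([]), {}
    if meta_path is not None and Path(meta_path).exists():
        d = json.loads(Path(meta_path).read_text())
        eig, params = np.asarray(d["eigenvalues"]), d.get("params", {})
    return GradientSet(G, eig, params)
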