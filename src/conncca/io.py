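"""Delimited-text readers and writers for the package's data types.

All formats are plain tab-separated text with full-precision numbers so
round trips are exact and files are diffable:

* RegionTimeSeries — header row of region labels, one row per sample;
  sampling rate and identity live in the run manifest.
* Connectome — square matrix with a label header row and a label index
  column.
* EdgeDataset — subjects × edges table plus a sidecar ``*.edges.tsv``
  naming the region pair of each column.
* manifests and calibrations — JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import Connectome, EdgeDataset
from .envelope import RegionTimeSeries

__all__ = [
    "write_timeseries", "read_timeseries",
    "write_connectome", "read_connectome",
    "write_edge_dataset", "read_edge_dataset",
    "write_manifest", "read_manifest",
]

_FLOAT_FMT = "%.17g"


def write_timeseries(ts: RegionTimeSeries, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(ts.labels) + "\n")
        np.savetxt(fh, ts.values, fmt=_FLOAT_FMT, delimiter="\t")


def read_timeseries(
    path,
    sampling_rate: float,
    subject_id: str | None = None,
    modality: str | None = None,
    band: str | None = None,
) -> RegionTimeSeries:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        labels = header.split("\t")
        if not labels or any(not lab for lab in labels):
            raise ValueError(f"{path}:1: malformed label header")
        try:
            values = np.loadtxt(fh, delimiter="\t", ndmin=2)
        except ValueError as exc:
            raise ValueError(f"{path}: malformed numeric body: {exc}") from exc
    if values.shape[1] != len(labels):
        raise ValueError(
            f"{path}:1: header names {len(labels)} regions but rows have "
            f"{values.shape[1]} columns"
        )
    return RegionTimeSeries(
        values=values, sampling_rate=sampling_rate, labels=labels,
        subject_id=subject_id, modality=modality, band=band,
    )


def write_connectome(conn: Connectome, path) -> None:
    df = pd.DataFrame(conn.matrix, index=conn.labels, columns=conn.labels)
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_connectome(path, kind: str, **meta) -> Connectome:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    labels = [str(c) for c in df.columns]
    if list(df.index.astype(str)) != labels:
        raise ValueError(f"{path}:1: row and column labels disagree")
    return Connectome(matrix=df.to_numpy(dtype=float), labels=labels, kind=kind, **meta)


def _edge_sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".edges.tsv")


def write_edge_dataset(ds: EdgeDataset, path) -> None:
    path = Path(path)
    index = ds.subject_ids or [f"sub-{s:02d}" for s in range(ds.n_subjects)]
    df = pd.DataFrame(ds.matrix, index=index)
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, header=False)
    pd.DataFrame(ds.edge_index, columns=["region_i", "region_j"]).to_csv(
        _edge_sidecar(path), sep="\t", index=False
    )


def read_edge_dataset(path, modality=None, band=None) -> EdgeDataset:
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", index_col=0, header=None, float_precision="round_trip"
    )
    edges = pd.read_csv(_edge_sidecar(path), sep="\t")
    if len(edges) != df.shape[1]:
        raise ValueError(
            f"{path}: {df.shape[1]} edge columns but sidecar names {len(edges)}"
        )
    return EdgeDataset(
        matrix=df.to_numpy(dtype=float),
        edge_index=[tuple(r) for r in edges.to_numpy()],
        modality=modality,
        band=band,
        subject_ids=[str(s) for s in df.index],
    )


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
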