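"""File I/O: HDF5 array containers with JSON sidecars, and plain TSV.

A time series is stored as an HDF5 file holding a float32 ``data`` dataset
(channels x samples) next to a ``<name>.json`` sidecar with the sampling
rate, channel labels, group tags and condition.  TSV round-trips are also
supported (samples as rows, one column per channel, header = labels).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datatypes import ConcatenatedDataset, RegionTimeSeries

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "write_tsv_timeseries",
    "read_tsv_timeseries",
    "write_dataset",
    "read_dataset",
    "write_json",
    "read_json",
]


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON-serialisable: {type(o)}")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_timeseries(ts: RegionTimeSeries, path: str | Path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ts.data.astype(np.float32))
    write_json(_sidecar(path), {
        "fs": ts.fs, "labels": ts.labels, "groups": ts.groups,
        "subject_id": ts.subject_id, "condition": ts.condition,
    })


def read_timeseries(path: str | Path) -> RegionTimeSeries:
    path = Path(path)
    if path.suffix in (".tsv", ".txt"):
        return read_tsv_timeseries(path)
    meta_path = _sidecar(path)
    if not meta_path.exists():
        raise FileNotFoundError(f"missing JSON sidecar {meta_path}")
    meta = read_json(meta_path)
    if "fs" not in meta:
        raise ValueError(f"sidecar {meta_path} lacks required key 'fs'")
    with h5py.File(path, "r") as f:
        data = np.asarray(f["data"], dtype=float)
    return RegionTimeSeries(
        data=data, fs=float(meta["fs"]), labels=list(meta.get("labels", [])),
        groups=list(meta.get("groups", [])), subject_id=meta.get("subject_id", "s0"),
        condition=meta.get("condition", "A"),
    )


def write_tsv_timeseries(ts: RegionTimeSeries, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(ts.data.T, columns=ts.labels).to_csv(path, sep="\t", index=False)
    write_json(_sidecar(path), {
        "fs": ts.fs, "labels": ts.labels, "groups": ts.groups,
        "subject_id": ts.subject_id, "condition": ts.condition,
    })


def read_tsv_timeseries(path: str | Path, fs: float | None = None) -> RegionTimeSeries:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    labels = header.split("\t")
    if len(labels) != len(set(labels)) or any(not l for l in labels):
        raise ValueError(f"{path}:1: malformed header (duplicate or empty labels)")
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as e:
        raise ValueError(f"{path}: malformed TSV: {e}") from e
    meta = {}
    if _sidecar(path).exists():
        meta = read_json(_sidecar(path))
    if fs is None:
        if "fs" not in meta:
            raise ValueError(f"sampling rate unknown: pass fs= or provide {_sidecar(path)} with 'fs'")
        fs = float(meta["fs"])
    return RegionTimeSeries(
        data=df.to_numpy(dtype=float).T, fs=fs, labels=labels,
        groups=list(meta.get("groups", [])), subject_id=meta.get("subject_id", path.stem),
        condition=meta.get("condition", "A"),
    )


def write_gamma_tsv(gamma: np.ndarray, boundaries: list[tuple[int, int]],
                    out_dir: str | Path, subject_ids: list[str] | None = None) -> list[Path]:
    """Export per-sample state probabilities as one TSV per subject."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    K = gamma.shape[1]
    for s, (a, b) in enumerate(boundaries):
        sid = subject_ids[s] if subject_ids else f"sub{s:02d}"
        p = out_dir / f"gamma_{sid}.tsv"
        pd.DataFrame(gamma[a:b], columns=[f"state{k}" for k in range(K)]).to_csv(
            p, sep="\t", index=False)
        paths.append(p)
    return paths


def write_dataset(ds: ConcatenatedDataset, path: str | Path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ds.data)
    write_json(_sidecar(path), {
        "fs": ds.fs, "labels": ds.labels, "groups": ds.groups,
        "subject_ids": ds.subject_ids, "condition": ds.condition,
        "boundaries": [list(b) for b in ds.boundaries],
    })


def read_dataset(path: str | Path) -> ConcatenatedDataset:
    path = Path(path)
    meta = read_json(_sidecar(path))
    with h5py.File(path, "r") as f:
        data = np.asarray(f["data"], dtype=float)
    return ConcatenatedDataset(
        data=data, fs=float(meta["fs"]),
        boundaries=[tuple(b) for b in meta["boundaries"]],
        labels=list(meta["labels"]), groups=list(meta["groups"]),
        subject_ids=list(meta["subject_ids"]), condition=meta["condition"],
    )
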