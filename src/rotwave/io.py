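"""Readers and writers for :class:`~rotwave.dataset.PopulationDataset`.

Two dialects are supported:

archive
    One compressed ``.npz`` file with arrays ``rates`` (c, t, n), ``dt_ms``
    (scalar), and optional ``event_index``, ``condition_labels``,
    ``neuron_ids``.  Lossless round trip.
delimited
    A directory with one tab-separated file per condition (rows = time
    samples, columns = neurons, header row = neuron ids) plus a
    ``metadata.json`` sidecar with ``dt_ms``, labels and the file order.
    Values survive a round trip to at least 12 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import PopulationDataset
from .errors import FormatError

__all__ = ["read_dataset", "write_dataset"]

_METADATA = "metadata.json"
_FLOAT_FMT = "%.17g"


def _infer_dialect(path: Path) -> str:
    if path.suffix == ".npz":
        return "archive"
    if path.is_dir() or not path.suffix:
        return "delimited"
    raise FormatError(f"cannot infer dialect from path {path!s}; pass dialect=")


def write_dataset(ds: PopulationDataset, path: str | Path, dialect: str | None = None) -> Path:
    """Write ``ds`` to ``path``; returns the path actually written."""
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "archive":
        return _write_archive(ds, path)
    if dialect == "delimited":
        return _write_delimited(ds, path)
    raise ValueError(f"unknown dialect {dialect!r}")


def read_dataset(path: str | Path, dialect: str | None = None) -> PopulationDataset:
    """Read a dataset written by :func:`write_dataset`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "archive":
        return _read_archive(path)
    if dialect == "delimited":
        return _read_delimited(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _write_archive(ds: PopulationDataset, path: Path) -> Path:
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    payload = {
        "rates": ds.rates,
        "dt_ms": np.asarray(ds.dt_ms),
        "condition_labels": np.asarray(ds.condition_labels, dtype=str),
        "neuron_ids": np.asarray(ds.neuron_ids, dtype=str),
    }
    if ds.event_index is not None:
        payload["event_index"] = np.asarray(int(ds.event_index))
    np.savez_compressed(path, **payload)
    return path


def _read_archive(path: Path) -> PopulationDataset:
    with np.load(path, allow_pickle=False) as npz:
        for key in ("rates", "dt_ms"):
            if key not in npz.files:
                raise FormatError(f"archive {path.name} is missing required field '{key}'")
        rates = npz["rates"]
        dt_ms = float(npz["dt_ms"])
        event = int(npz["event_index"]) if "event_index" in npz.files else None
        labels = tuple(npz["condition_labels"].tolist()) if "condition_labels" in npz.files else ()
        ids = tuple(npz["neuron_ids"].tolist()) if "neuron_ids" in npz.files else ()
    return PopulationDataset(rates, dt_ms, event_index=event,
                             condition_labels=labels, neuron_ids=ids)


def _condition_filename(index: int) -> str:
    return f"condition_{index:03d}.tsv"


def _write_delimited(ds: PopulationDataset, path: Path) -> Path:
    path.mkdir(parents=True, exist_ok=True)
    files = []
    for l in range(ds.n_conditions):
        fname = _condition_filename(l)
        frame = pd.DataFrame(ds.rates[l], columns=list(ds.neuron_ids))
        frame.to_csv(path / fname, sep="\t", index=False, float_format=_FLOAT_FMT)
        files.append(fname)
    meta = {
        "dt_ms": ds.dt_ms,
        "event_index": ds.event_index,
        "condition_labels": list(ds.condition_labels),
        "files": files,
    }
    (path / _METADATA).write_text(json.dumps(meta, indent=1))
    return path


def _read_delimited(path: Path) -> PopulationDataset:
    meta_path = path / _METADATA
    if not meta_path.exists():
        raise FormatError(f"delimited directory {path.name} is missing '{_METADATA}'")
    meta = json.loads(meta_path.read_text())
    for key in ("dt_ms", "condition_labels", "files"):
        if key not in meta:
            raise FormatError(f"{_METADATA} is missing required field '{key}'")
    frames = []
    columns = None
    for fname in meta["files"]:
        fpath = path / fname
        if not fpath.exists():
            raise FormatError(f"condition file '{fname}' listed in metadata is absent")
        frame = pd.read_csv(fpath, sep="\t")
        if columns is None:
            columns = list(frame.columns)
        elif list(frame.columns) != columns:
            raise FormatError(
                f"condition file '{fname}' has neuron columns inconsistent with "
                f"'{meta['files'][0]}'"
            )
        frames.append(frame.to_numpy(dtype=float))
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise FormatError("condition files differ in number of time samples")
    rates = np.stack(frames)
    return PopulationDataset(
        rates,
        float(meta["dt_ms"]),
        event_index=meta.get("event_index"),
        condition_labels=tuple(meta["condition_labels"]),
        neuron_ids=tuple(str(c) for c in columns),
    )
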