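"""Single-file HDF5 container for datasets and results.

Layout: one group per stage (``/stimulus``, ``/movie``, ``/rois``, ``/traces``,
``/truth``, ``/fits`` — plus anything else the caller puts in the bundle).  A
bundle is a nested dict whose leaves are numpy arrays, scalars, strings or
pandas DataFrames (stored as column datasets with a ``kind='table'`` marker).
Round trips are lossless for numeric payloads, and unknown groups written by
other tools are preserved on read.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import ContainerSchemaError

__all__ = ["SCHEMA_VERSION", "write_container", "read_container", "require_groups"]

SCHEMA_VERSION = "1"


def _write_node(grp: h5py.Group, key: str, value) -> None:
    if isinstance(value, pd.DataFrame):
        sub = grp.create_group(key)
        sub.attrs["kind"] = "table"
        sub.attrs["columns"] = list(value.columns)
        for col in value.columns:
            data = value[col].to_numpy()
            if data.dtype == object or data.dtype.kind in ("U", "S"):
                sub.create_dataset(col, data=np.asarray(data, dtype=h5py.string_dtype()))
            else:
                sub.create_dataset(col, data=data)
    elif isinstance(value, dict):
        sub = grp.create_group(key)
        for k, v in value.items():
            _write_node(sub, k, v)
    elif isinstance(value, str):
        grp.attrs[key] = value
    elif np.isscalar(value):
        grp.attrs[key] = value
    elif value is None:
        pass
    else:
        arr = np.asarray(value)
        if arr.dtype == object or arr.dtype.kind in ("U", "S"):
            grp.create_dataset(key, data=np.asarray(arr, dtype=h5py.string_dtype()))
        else:
            grp.create_dataset(key, data=arr)


def write_container(bundle: dict, path: str | Path) -> Path:
    """Write a nested bundle to an HDF5 file; returns the path."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        for key, value in bundle.items():
            _write_node(f, key, value)
    return path


def _read_node(node):
    if isinstance(node, h5py.Dataset):
        data = node[()]
        if node.dtype.kind == "O" or h5py.check_string_dtype(node.dtype):
            return np.array([v.decode() if isinstance(v, bytes) else v for v in np.ravel(data)]).reshape(np.shape(data))
        return data
    out = {}
    if node.attrs.get("kind") == "table":
        cols = list(node.attrs["columns"])
        return pd.DataFrame({c: np.asarray(_read_node(node[c])) for c in cols})
    for k, v in node.attrs.items():
        if k in ("kind", "columns", "schema_version"):
            continue
        out[k] = v.decode() if isinstance(v, bytes) else v
    for k in node.keys():
        out[k] = _read_node(node[k])
    return out


def read_container(path: str | Path) -> dict:
    """Read a container back into a nested bundle dict."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if isinstance(version, bytes):
            version = version.decode()
        if version != SCHEMA_VERSION:
            raise ContainerSchemaError(
                f"container schema version {version!r} does not match "
                f"library schema version {SCHEMA_VERSION!r}"
            )
        return _read_node(f)


def require_groups(bundle: dict, *names: str) -> None:
    """Raise a schema error naming the first missing required group."""
    for name in names:
        if name not in bundle:
            raise ContainerSchemaError(f"container is missing required group {name!r}")
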