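"""Shared file formats: TSV tables, the hierarchical recording container,
and results-bundle serialization.

Events and channel tables are tab-separated values with fixed required
headers (a BIDS-events-like dialect); times are seconds, sample indexing is
0-based, epoch windows are closed-open ``[start, end)``.  Recordings travel
in a single HDF5 container (see :mod:`hierseq.synth`).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "write_table",
    "read_table",
    "require_columns",
    "table_to_group",
    "table_from_group",
]


class SchemaError(ValueError):
    """A file or table does not match the expected schema."""


def require_columns(df: pd.DataFrame, columns, what: str = "table") -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {missing}")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_table(path, required=None, what: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    if required is not None:
        require_columns(df, required, what or str(path))
    return df


def table_to_group(df: pd.DataFrame, group: h5py.Group) -> None:
    """Store a DataFrame column-wise in an HDF5 group (strings as UTF-8)."""
    group.attrs["columns"] = list(df.columns)
    for col in df.columns:
        values = df[col].to_numpy()
        if values.dtype == object or values.dtype.kind in "US":
            dt = h5py.string_dtype(encoding="utf-8")
            strings = np.array([str(v) for v in values], dtype=object)
            group.create_dataset(col, data=strings, dtype=dt)
        else:
            group.create_dataset(col, data=values)


def table_from_group(group: h5py.Group) -> pd.DataFrame:
    columns = list(group.attrs["columns"])
    data = {}
    for col in columns:
        if col not in group:
            raise SchemaError(f"HDF5 group {group.name!r} is missing column {col!r}")
        arr = group[col][()]
        if arr.dtype.kind in ("O", "S"):
            arr = np.array([v.decode() if isinstance(v, bytes) else str(v) for v in arr])
        data[col] = arr
    return pd.DataFrame(data, columns=columns)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"cannot serialize {type(o)}")
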