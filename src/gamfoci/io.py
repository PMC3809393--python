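"""Tab-separated interchange formats and JSON result serialisation.

All tables are TSV with a header row and dot-decimal floats (locale
independent).  Malformed rows are reported with their 1-based line
number.  ``read(write(x))`` round-trips every record type.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import math
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .simulate import MicrocolonyTrace

__all__ = [
    "read_tsv",
    "write_table",
    "read_dose_table",
    "read_focus_calls",
    "read_ct_table",
    "write_traces",
    "read_traces",
    "write_result_json",
    "write_image",
    "read_image",
]

TRACE_FRAME_SCHEMA = {
    "colony_id": str,
    "time_h": float,
    "n_cells": int,
    "cum_divisions": int,
    "cum_foci": int,
}
TRACE_EVENT_SCHEMA = {"colony_id": str, "time_h": float, "kind": str, "cell_id": str}
DOSE_SCHEMA = {"dose_gy": float, "mean_foci": float, "sd_foci": float, "n_cells": int}
FOCUS_SCHEMA = {
    "cell_id": str,
    "channel": str,
    "x_um": float,
    "y_um": float,
    "intensity": float,
}
CT_SCHEMA = {"sample": str, "locus": str, "ct": float}


class TableFormatError(ValueError):
    """Malformed interchange table; message names the offending line."""


def read_tsv(path: str | Path, schema: dict[str, Callable]) -> pd.DataFrame:
    """Read a TSV with the given column schema, validating row by row."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise TableFormatError(f"{path}: empty file") from None
        expected = list(schema)
        if header != expected:
            raise TableFormatError(
                f"{path}: line 1: header {header!r} does not match expected {expected!r}"
            )
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(expected):
                raise TableFormatError(
                    f"{path}: line {lineno}: expected {len(expected)} fields, got {len(row)}"
                )
            parsed = []
            for name, conv, raw in zip(expected, schema.values(), row):
                try:
                    val = conv(raw)
                except ValueError:
                    raise TableFormatError(
                        f"{path}: line {lineno}: cannot parse {name}={raw!r}"
                    ) from None
                if isinstance(val, float) and not math.isfinite(val):
                    raise TableFormatError(
                        f"{path}: line {lineno}: non-finite value {name}={raw!r}"
                    )
                parsed.append(val)
            rows.append(parsed)
    df = pd.DataFrame(rows, columns=expected)
    for name, conv in schema.items():
        if conv is float:
            df[name] = df[name].astype(float)
        elif conv is int:
            df[name] = df[name].astype(int)
    return df


def write_table(df: pd.DataFrame, path: str | Path, schema: dict[str, Callable]) -> None:
    """Write the schema's columns of ``df`` as TSV (header, dot decimals)."""
    cols = list(schema)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"table missing columns {missing}")
    df[cols].to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_dose_table(path: str | Path) -> pd.DataFrame:
    return read_tsv(path, DOSE_SCHEMA)


def read_focus_calls(path: str | Path) -> pd.DataFrame:
    return read_tsv(path, FOCUS_SCHEMA)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    return read_tsv(path, CT_SCHEMA)


def write_traces(
    traces: Sequence[MicrocolonyTrace],
    frames_path: str | Path,
    events_path: str | Path,
) -> None:
    """Write microcolony traces as a frames TSV and an event-log TSV."""
    frames = []
    events = []
    for tr in traces:
        f = tr.frames.copy()
        f.insert(0, "colony_id", tr.colony_id)
        frames.append(f)
        e = tr.events.copy()
        e.insert(0, "colony_id", tr.colony_id)
        events.append(e)
    write_table(pd.concat(frames, ignore_index=True), frames_path, TRACE_FRAME_SCHEMA)
    write_table(pd.concat(events, ignore_index=True), events_path, TRACE_EVENT_SCHEMA)


def read_traces(
    frames_path: str | Path, events_path: str | Path | None = None
) -> list[MicrocolonyTrace]:
    """Read traces back; the event log is optional (empty if absent)."""
    frames = read_tsv(frames_path, TRACE_FRAME_SCHEMA)
    if events_path is not None:
        events = read_tsv(events_path, TRACE_EVENT_SCHEMA)
    else:
        events = pd.DataFrame(columns=list(TRACE_EVENT_SCHEMA))
    traces = []
    for cid, grp in frames.groupby("colony_id", sort=True):
        ev = events[events["colony_id"] == cid].drop(columns="colony_id")
        traces.append(
            MicrocolonyTrace(
                colony_id=str(cid),
                frames=grp.drop(columns="colony_id").reset_index(drop=True),
                events=ev.reset_index(drop=True),
            )
        )
    return traces


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    return obj


def write_result_json(result, path: str | Path) -> None:
    """Serialise a result dataclass (or dict) deterministically to JSON."""
    with Path(path).open("w") as fh:
        json.dump(_jsonable(result), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Single-channel TIFF (float32 photon counts or integer labels)."""
    import tifffile

    arr = np.asarray(image)
    if not np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float32)
    tifffile.imwrite(str(path), arr)


def read_image(path: str | Path) -> np.ndarray:
    import tifffile

    return tifffile.imread(str(path))
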