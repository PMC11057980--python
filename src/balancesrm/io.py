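"""Delimited-text I/O for time series and fit results.

Canonical time-series dialect: two comment header lines declaring the
sampling rate and epoch origin, then a ``time_ms,value`` CSV body::

    # fs=1000.0
    # t0=-400.0
    time_ms,value
    -400,0.0
    ...

Round-trips are lossless to float precision (values written with repr-level
accuracy); malformed headers and non-uniform time columns are rejected with
line-numbered errors.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np

from .timeseries import TimeSeries

__all__ = ["read_timeseries", "write_timeseries", "write_json", "read_json"]

PathLike = Union[str, Path]


def write_timeseries(ts: TimeSeries, path: PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    t = ts.times
    with open(path, "w") as fh:
        fh.write(f"# fs={float(ts.fs)!r}\n# t0={float(ts.t0)!r}\ntime_ms,value\n")
        for ti, vi in zip(t, ts.values):
            fh.write(f"{float(ti)!r},{float(vi)!r}\n")


def _header_value(line: str, key: str, lineno: int) -> float:
    prefix = f"# {key}="
    if not line.startswith(prefix):
        raise ValueError(f"line {lineno}: expected header '{prefix}<number>', got {line!r}")
    try:
        return float(line[len(prefix):])
    except ValueError as exc:
        raise ValueError(f"line {lineno}: non-numeric {key} header") from exc


def read_timeseries(path: PathLike) -> TimeSeries:
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 4:
        raise ValueError(f"{path}: too short to be a time-series file")
    fs = _header_value(lines[0], "fs", 1)
    t0 = _header_value(lines[1], "t0", 2)
    if lines[2].strip() != "time_ms,value":
        raise ValueError(f"line 3: expected column header 'time_ms,value', got {lines[2]!r}")
    times = []
    values = []
    for i, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise ValueError(f"line {i}: expected 'time_ms,value' row")
        try:
            times.append(float(parts[0]))
            values.append(float(parts[1]))
        except ValueError as exc:
            raise ValueError(f"line {i}: non-numeric row {line!r}") from exc
    t = np.asarray(times)
    dt = 1000.0 / fs
    expected = t0 + np.arange(t.size) * dt
    if t.size < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    if np.any(np.abs(t - expected) > 1e-6 * max(1.0, dt)):
        raise ValueError(
            f"{path}: time column is not uniform at fs={fs} Hz from t0={t0} ms "
            "(shuffled rows or header mismatch)"
        )
    return TimeSeries(np.asarray(values), fs, t0)


def write_json(obj, path: PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, allow_nan=True)
        fh.write("\n")


def read_json(path: PathLike):
    with open(path) as fh:
        return json.load(fh)
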