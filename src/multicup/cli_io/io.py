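"""Plain-text I/O: CSV series, solubility tables, configs and manifests.

CSV dialect is comma-separated, period decimal, UTF-8, header required.
Time columns are named ``time_min`` or ``time_h`` so the unit always
travels with the file.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from ..errors import ParseError
from ..solubility import SolubilityPoint
from ..timeseries import TimeSeries

_TIME_COLS = {"time_min": "min", "time_h": "h"}


def read_timeseries(
    path,
    value_col: str = "value",
    label: Optional[str] = None,
) -> TimeSeries:
    """Read one series from CSV; the time column names its unit.

    Rows must be strictly increasing in time; shuffled or duplicated rows
    raise :class:`ParseError` naming the first offending row.
    """
    df = pd.read_csv(path)
    time_col = next((c for c in df.columns if c in _TIME_COLS), None)
    if time_col is None:
        raise ParseError(f"{path}: no time_min/time_h column (got {list(df.columns)})")
    if value_col not in df.columns:
        raise ParseError(f"{path}: missing value column {value_col!r}")
    if label is not None and "label" in df.columns:
        df = df[df["label"] == label]
    t = df[time_col].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        # bad[0] indexes the first offending pair; +3 converts to the file
        # line of the second member (1-based, after the header)
        raise ParseError(
            f"{path}: times not strictly increasing at data row {bad[0] + 3}"
        )
    return TimeSeries(
        t,
        df[value_col].to_numpy(dtype=float),
        time_unit=_TIME_COLS[time_col],
        label=label or (str(df["label"].iloc[0]) if "label" in df.columns else ""),
    )


def write_timeseries(ts: TimeSeries, path, value_col: str = "value") -> None:
    df = pd.DataFrame({f"time_{ts.time_unit}": ts.time, value_col: ts.value})
    if ts.label:
        df["label"] = ts.label
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_timeseries_bundle(series: Dict[str, TimeSeries], path) -> None:
    """Stack several series sharing a time unit into one long-format CSV."""
    frames = []
    for name, ts in series.items():
        frames.append(pd.DataFrame({
            f"time_{ts.time_unit}": ts.time,
            "value": ts.value,
            "label": name,
        }))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_solubility_table(path) -> Dict[str, List[SolubilityPoint]]:
    """Read a pH-solubility table: columns pH, solubility_ug_per_ml[, group]."""
    df = pd.read_csv(path)
    for col in ("pH", "solubility_ug_per_ml"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    if "group" not in df.columns:
        df["group"] = "all"
    out: Dict[str, List[SolubilityPoint]] = {}
    for i, row in df.iterrows():
        try:
            pt = SolubilityPoint(pH=float(row["pH"]),
                                 solubility=float(row["solubility_ug_per_ml"]))
        except Exception as exc:
            raise ParseError(f"{path}: invalid data row {i + 2}: {exc}") from exc
        out.setdefault(str(row["group"]), []).append(pt)
    return out


def read_config(path) -> dict:
    """Read a flat plain-text config: JSON, or ``key = value`` lines."""
    text = Path(path).read_text()
    stripped = text.lstrip()
    if stripped.startswith("{"):
        return json.loads(text)
    out = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParseError(f"{path}: line {lineno}: expected key = value")
        key, _, val = line.partition("=")
        val = val.strip()
        try:
            out[key.strip()] = json.loads(val)
        except json.JSONDecodeError:
            out[key.strip()] = val
    return out


def write_manifest(path, **fields) -> None:
    """Record parameters, seed and stage outputs for exact reruns."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(fields, fh, indent=2, default=str, sort_keys=True)
        fh.write("\n")
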