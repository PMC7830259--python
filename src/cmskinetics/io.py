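"""Delimited-text readers and writers for the pipeline's artifacts.

Interchange formats are plain CSV with explicit headers:

* concentration series — ``time_min,value,unit,temperature_C``;
* calibration tables — ``analyte,run,level_ug_mL,response``;
* reports — key-value JSON documents plus human-readable CSV tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import ConcentrationSeries

__all__ = [
    "read_series",
    "write_series",
    "read_calibration_table",
    "write_calibration_table",
    "write_json_report",
    "read_json_report",
]

SERIES_COLUMNS = ["time_min", "value", "unit", "temperature_C"]
CALIBRATION_COLUMNS = ["analyte", "run", "level_ug_mL", "response"]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def read_series(path) -> ConcentrationSeries:
    """Read a concentration series from CSV.

    Rows out of time order are sorted with a warning; missing columns and
    non-numeric cells raise :class:`ParseError` naming the line (1-based,
    header included).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing = [c for c in SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: header is missing column(s) {missing}")
    for col in ("time_min", "value", "temperature_C"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 zero-based
            raise ParseError(
                f"{path}: non-numeric {col!r} value {df[col][bad.idxmax()]!r} "
                f"on line {line}"
            )
        df[col] = parsed
    if df["time_min"].isna().any() or df["value"].isna().any():
        line = int(df[["time_min", "value"]].isna().any(axis=1).idxmax()) + 2
        raise ParseError(f"{path}: empty time/value cell on line {line}")
    if not df["time_min"].is_monotonic_increasing:
        import warnings

        warnings.warn(f"{path}: rows out of time order; sorting", stacklevel=2)
        df = df.sort_values("time_min", kind="stable")
    units = df["unit"].unique()
    if len(units) != 1:
        raise ParseError(f"{path}: mixed units {list(units)} in one series")
    temps = df["temperature_C"].unique()
    if len(temps) != 1:
        raise ParseError(f"{path}: mixed temperatures {list(temps)} in one series")
    return ConcentrationSeries(
        times=df["time_min"].to_numpy(dtype=float),
        values=df["value"].to_numpy(dtype=float),
        unit_tag=str(units[0]),
        temperature_C=float(temps[0]),
    )


def write_series(series: ConcentrationSeries, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "time_min": series.times,
            "value": series.values,
            "unit": series.unit_tag,
            "temperature_C": series.temperature_C,
        }
    ).to_csv(path, index=False)
    return path


def read_calibration_table(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, skipinitialspace=True)
    missing = [c for c in CALIBRATION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: header is missing column(s) {missing}")
    for col in ("level_ug_mL", "response"):
        if not np.issubdtype(df[col].dtype, np.number):
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            line = int(bad.idxmax()) + 2
            raise ParseError(f"{path}: non-numeric {col!r} on line {line}")
    return df[CALIBRATION_COLUMNS]


def write_calibration_table(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table[CALIBRATION_COLUMNS].to_csv(path, index=False)
    return path


def write_json_report(obj: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def read_json_report(path) -> dict:
    return json.loads(Path(path).read_text())
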