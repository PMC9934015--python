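"""Delimited-text readers and writers for tower and plot tables.

Half-hourly tables use FLUXNET-style columns (TIMESTAMP_START, NEE, SW_IN,
TA, VPD, USTAR) with -9999 (configurable) or empty cells for missing
values; plot tables are plain CSV, one file per measurement class; truth
bundles are written as plain-text key-value files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_halfhourly",
    "write_halfhourly",
    "write_plot_tables",
    "read_plot_tables",
    "write_truth_bundle",
]

_TS_FORMAT = "%Y%m%d%H%M"
PLOT_TABLE_NAMES = ("collars", "stems", "census", "deadwood",
                    "deadwood_inventory", "leaf", "components")


def read_halfhourly(path, na_values=(-9999, -9999.0, "-9999"), sep=",") -> pd.DataFrame:
    """Read a FLUXNET-style half-hourly table.

    The index is the half-hour-ending timestamp parsed from TIMESTAMP_END
    when present, else TIMESTAMP_START + 30 min.
    """
    df = pd.read_csv(path, sep=sep, na_values=list(na_values))
    if "TIMESTAMP_END" in df:
        idx = pd.to_datetime(df["TIMESTAMP_END"].astype("int64").astype(str),
                             format=_TS_FORMAT)
    elif "TIMESTAMP_START" in df:
        idx = pd.to_datetime(df["TIMESTAMP_START"].astype("int64").astype(str),
                             format=_TS_FORMAT) + pd.Timedelta(minutes=30)
    else:
        raise ValueError("need TIMESTAMP_START or TIMESTAMP_END column")
    df.index = pd.DatetimeIndex(idx, name="time")
    return df


def write_halfhourly(df: pd.DataFrame, path, na_rep="-9999", sep=",") -> None:
    """Write a half-hourly table with FLUXNET-style missing-value markers."""
    out = df.copy()
    if "TIMESTAMP_END" not in out:
        out.insert(0, "TIMESTAMP_END", out.index.strftime(_TS_FORMAT))
    if "TIMESTAMP_START" not in out:
        out.insert(0, "TIMESTAMP_START",
                   (out.index - pd.Timedelta(minutes=30)).strftime(_TS_FORMAT))
    out.to_csv(path, sep=sep, na_rep=na_rep, index=False, float_format="%.10g")


def write_plot_tables(tables: dict, out_dir) -> None:
    """Write the plot measurement tables, one CSV per measurement class."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False, float_format="%.10g")


def read_plot_tables(in_dir, names=PLOT_TABLE_NAMES) -> dict:
    """Read back a directory of plot measurement tables."""
    path = Path(in_dir)
    return {name: pd.read_csv(path / f"{name}.csv") for name in names
            if (path / f"{name}.csv").exists()}


def _flatten(prefix, obj, rows):
    if isinstance(obj, dict):
        for k, v in obj.items():
            _flatten(f"{prefix}.{k}" if prefix else str(k), v, rows)
    elif isinstance(obj, (list, tuple, np.ndarray)):
        rows.append((prefix, " ".join(str(x) for x in obj)))
    else:
        rows.append((prefix, str(obj)))


def write_truth_bundle(truth, path) -> None:
    """Write a truth bundle's parameters as a plain-text key-value file."""
    rows: list[tuple[str, str]] = []
    _flatten("", truth.as_dict(), rows)
    with open(path, "w") as fh:
        for key, val in rows:
            fh.write(f"{key} = {val}\n")
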