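"""Strict CSV I/O for daily series tables, forecasts and ledgers."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from bloodstock.inventory import SimulationLedger

__all__ = [
    "read_daily_csv",
    "write_daily_csv",
    "write_ledger",
    "write_summary_json",
]


def read_daily_csv(path) -> pd.DataFrame:
    """Read a daily series table with schema validation.

    Requires a ``date`` first column (ISO dates, strictly consecutive days)
    and non-negative numeric count columns; violations raise with the
    offending column and row named.
    """
    df = pd.read_csv(path)
    if "date" not in df.columns:
        raise ValueError(f"{path}: missing required column 'date'")
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: unparseable date: {exc}") from exc
    if len(df) > 1:
        deltas = df["date"].diff().dropna()
        bad = np.flatnonzero(deltas != pd.Timedelta(days=1))
        if len(bad):
            raise ValueError(
                f"{path}: date gap at row {bad[0] + 1} "
                f"({df['date'].iloc[bad[0] + 1].date()})"
            )
    for c in df.columns:
        if c == "date":
            continue
        col = pd.to_numeric(df[c], errors="coerce")
        neg = col < 0
        if neg.any():
            row = int(np.argmax(neg.to_numpy()))
            raise ValueError(f"{path}: negative count in column {c!r}, row {row}")
        df[c] = col
    return df


def write_daily_csv(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)


def write_ledger(ledger: SimulationLedger, path) -> None:
    """Per-day ledger CSV: date, weekday, demand, order, arrival, purchase,
    waste, stock."""
    frame = ledger.frame()
    frame["date"] = pd.to_datetime(frame["date"]).dt.strftime("%Y-%m-%d")
    cols = ["date", "weekday", "demand", "order", "arrival", "purchase", "waste", "stock"]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame[cols].to_csv(path, index=False)


def write_summary_json(summary: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(summary, indent=2, default=default) + "\n")
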