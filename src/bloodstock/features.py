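"""Design-matrix construction for the demand models.

Cleaning and feature engineering for a daily platelet table: zero
imputation, removal of sparse or discontinuous covariates, a squared-Pearson
correlation screen against platelet use, the PL7 predictor (mean
transfusions over the strictly previous 7 days), weekday dummy variables
(Sunday reference), and the 2- and 4-day demand targets

    y2(i) = u(i+1) + u(i+2)
    y4(i) = u(i+1) + u(i+2) + u(i+3) + u(i+4)

where u is the number of platelet units transfused per day.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "impute_zeros",
    "filter_sparse_features",
    "filter_discontinuous_features",
    "correlation_screen",
    "add_rolling_mean",
    "add_weekday_dummies",
    "build_targets",
    "build_design_matrix",
    "WEEKDAY_COLUMNS",
    "feature_columns",
]

#: Indicator columns added by :func:`add_weekday_dummies`; Sunday (d_w = 0)
#: is the dropped reference category.
WEEKDAY_COLUMNS = (
    "weekday_monday",
    "weekday_tuesday",
    "weekday_wednesday",
    "weekday_thursday",
    "weekday_friday",
    "weekday_saturday",
)

_NON_FEATURE = {"date", "demand", "y2", "y4"}


def _check_contiguous(table: pd.DataFrame) -> None:
    dates = pd.to_datetime(table["date"])
    if len(dates) > 1:
        deltas = dates.diff().dropna()
        if not (deltas == pd.Timedelta(days=1)).all():
            bad = dates[np.flatnonzero(deltas != pd.Timedelta(days=1)) + 1]
            raise ValueError(
                f"dates must be consecutive days; gap before {bad.iloc[0].date()}"
            )


def _covariate_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in _NON_FEATURE]


def feature_columns(matrix: pd.DataFrame) -> list[str]:
    """Predictor columns of a design matrix (everything but date, demand
    and the targets)."""
    return _covariate_columns(matrix)


def impute_zeros(raw: pd.DataFrame) -> pd.DataFrame:
    """Replace missing cells in count columns with 0.

    Hospital records often encode "no events" as an absent row rather than
    an explicit zero, so missingness is informative of a zero count, not of
    lost data.  Dates must already be a contiguous daily calendar; a gap is
    a contract violation, not something to impute.
    """
    _check_contiguous(raw)
    out = raw.copy()
    count_cols = [c for c in out.columns if c != "date"]
    out[count_cols] = out[count_cols].fillna(0)
    for c in count_cols:
        if (out[c] < 0).any():
            row = int(np.argmax(out[c].to_numpy() < 0))
            raise ValueError(f"negative count in column {c!r} at row {row}")
    return out


def filter_sparse_features(
    table: pd.DataFrame, min_nonzero: int = 400
) -> pd.DataFrame:
    """Drop covariate columns with fewer than ``min_nonzero`` nonzero values.

    Near-empty covariates carry no usable signal. The ``demand`` column is
    never dropped.
    """
    drop = [
        c
        for c in _covariate_columns(table)
        if int((table[c] != 0).sum()) < min_nonzero
    ]
    return table.drop(columns=drop)


def filter_discontinuous_features(
    table: pd.DataFrame, max_zero_run: int = 365
) -> pd.DataFrame:
    """Drop covariates with a run of >= ``max_zero_run`` consecutive zeros.

    A year-long all-zero stretch indicates the source (e.g. a hospital
    department) did not exist for part of the observation period.
    """
    drop = []
    for c in _covariate_columns(table):
        x = (table[c].to_numpy() == 0).astype(np.int64)
        # longest run of 1s
        run = best = 0
        for v in x:
            run = run + 1 if v else 0
            best = max(best, run)
        if best >= max_zero_run:
            drop.append(c)
    return table.drop(columns=drop)


def _r2_with_demand(x: np.ndarray, u: np.ndarray) -> float:
    if x.std() == 0 or u.std() == 0:
        return 0.0
    r = float(np.corrcoef(x, u)[0, 1])
    return r * r


def correlation_screen(
    table: pd.DataFrame, r2_threshold: float = 0.2
) -> pd.DataFrame:
    """Keep covariates with squared Pearson correlation to platelet use
    >= ``r2_threshold``.

    The screen is sign-agnostic (anticorrelated predictors are kept) and a
    zero-variance column counts as r^2 = 0. ``demand`` is always retained.
    """
    u = table["demand"].to_numpy(dtype=float)
    # engineered predictors (PL7, weekday dummies) are added unconditionally
    # and never screened
    drop = [
        c
        for c in _covariate_columns(table)
        if c not in WEEKDAY_COLUMNS
        and c != "PL7"
        and _r2_with_demand(table[c].to_numpy(dtype=float), u) < r2_threshold
    ]
    return table.drop(columns=drop)


def add_rolling_mean(table: pd.DataFrame, window: int = 7) -> pd.DataFrame:
    """Add PL7: the mean demand over the strictly previous ``window`` days.

    PL7(i) averages days i-window .. i-1, excluding day i itself so the
    predictor never contains the outcome it helps predict. The first
    ``window`` rows, which lack a full history, are dropped.
    """
    if len(table) < window + 1:
        raise ValueError(f"need at least {window + 1} rows, got {len(table)}")
    out = table.copy()
    out["PL7"] = (
        out["demand"].rolling(window=window, min_periods=window).mean().shift(1)
    )
    return out.iloc[window:].reset_index(drop=True)


def add_weekday_dummies(table: pd.DataFrame) -> pd.DataFrame:
    """Add six weekday indicators with Sunday (d_w = 0) as the reference."""
    out = table.copy()
    dw = (pd.to_datetime(out["date"]).dt.dayofweek + 1) % 7
    for k, name in enumerate(WEEKDAY_COLUMNS, start=1):
        out[name] = (dw == k).astype(np.int64)
    return out


def build_targets(table: pd.DataFrame) -> pd.DataFrame:
    """Append the 2- and 4-day-ahead demand sums and drop incomplete rows.

    Row i predicts the future: y2 sums demand on days i+1 and i+2, y4 on
    days i+1 .. i+4.  The last 4 rows lack a full 4-day window and are
    excluded.
    """
    if len(table) < 5:
        raise ValueError("need at least 5 rows to build 4-day targets")
    out = table.copy()
    u = out["demand"]
    out["y2"] = u.shift(-1) + u.shift(-2)
    out["y4"] = u.shift(-1) + u.shift(-2) + u.shift(-3) + u.shift(-4)
    out = out.iloc[:-4].reset_index(drop=True)
    out["y2"] = out["y2"].astype(np.int64)
    out["y4"] = out["y4"].astype(np.int64)
    return out


def build_design_matrix(
    raw: pd.DataFrame,
    *,
    min_nonzero: int = 400,
    max_zero_run: int = 365,
    r2_threshold: float | None = None,
    pl7_window: int = 7,
) -> pd.DataFrame:
    """Full feature pipeline: impute, filter, PL7, weekday dummies, targets.

    ``r2_threshold=None`` (the default) leaves the correlation screen to the
    model-fitting stage, where it is recomputed on each training span to
    avoid test-set leakage under rolling-origin evaluation; passing a value
    screens once globally on the whole table instead.
    """
    t = impute_zeros(raw)
    t = filter_sparse_features(t, min_nonzero=min_nonzero)
    t = filter_discontinuous_features(t, max_zero_run=max_zero_run)
    if r2_threshold is not None:
        t = correlation_screen(t, r2_threshold=r2_threshold)
    t = add_rolling_mean(t, window=pl7_window)
    t = add_weekday_dummies(t)
    return build_targets(t)
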