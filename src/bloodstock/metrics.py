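"""Forecast-accuracy measures with bootstrap CIs and CI-derived p values.

Accuracy is summarized by RMSE, the squared Pearson correlation of
predictions and truth (r^2), and MAPE.  Confidence intervals come from a
percentile bootstrap over days.  Two models are compared by converting each
metric's 95% CI back to a standard error and forming a two-sided Normal z
test on the difference (the Altman-Bland CI-to-p recipe).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "EvalReport",
    "rmse",
    "r_squared",
    "mape",
    "compute_metrics",
    "bootstrap_ci",
    "ci_difference_pvalue",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvalReport:
    """Point estimates and 95% CIs for one model/horizon combination."""

    model: str
    horizon: int
    n_days: int
    rmse: float
    rmse_ci: tuple
    r2: float
    r2_ci: tuple
    mape: float
    mape_ci: tuple
    n_zero_truth_excluded: int = 0

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "horizon": self.horizon,
            "n_days": self.n_days,
            "rmse": self.rmse,
            "rmse_lo": self.rmse_ci[0],
            "rmse_hi": self.rmse_ci[1],
            "r2": self.r2,
            "r2_lo": self.r2_ci[0],
            "r2_hi": self.r2_ci[1],
            "mape": self.mape,
            "mape_lo": self.mape_ci[0],
            "mape_hi": self.mape_ci[1],
        }


def rmse(pred: np.ndarray, true: np.ndarray) -> float:
    pred, true = np.asarray(pred, float), np.asarray(true, float)
    return float(np.sqrt(np.mean((pred - true) ** 2)))


def r_squared(pred: np.ndarray, true: np.ndarray) -> float:
    """Squared Pearson correlation of predictions and truth."""
    pred, true = np.asarray(pred, float), np.asarray(true, float)
    if pred.std() == 0 or true.std() == 0:
        return 1.0 if np.allclose(pred, true) else 0.0
    r = float(np.corrcoef(pred, true)[0, 1])
    return r * r


def mape(pred: np.ndarray, true: np.ndarray) -> float:
    """Mean absolute percent error; days with zero truth are excluded."""
    pred, true = np.asarray(pred, float), np.asarray(true, float)
    mask = true != 0
    n_zero = int((~mask).sum())
    if not mask.any():
        raise ValueError("MAPE undefined: all truth values are zero")
    if n_zero:
        log.info("MAPE: excluded %d day(s) with zero truth", n_zero)
    return float(np.mean(np.abs(pred[mask] - true[mask]) / true[mask]) * 100.0)


def compute_metrics(
    pred: np.ndarray,
    true: np.ndarray,
    *,
    model: str = "model",
    horizon: int = 2,
    n_boot: int = 2000,
    seed: int = 0,
) -> EvalReport:
    """Evaluate a forecast against the realized demand sums.

    Point estimates plus 95% percentile-bootstrap CIs over days for all
    three metrics.  ``pred``/``true`` must be aligned per-day series of
    equal length >= 2.
    """
    pred, true = np.asarray(pred, float), np.asarray(true, float)
    if pred.shape != true.shape:
        raise ValueError("pred and true must be aligned and equal length")
    if len(pred) < 2:
        raise ValueError("need at least 2 days")
    pairs = np.column_stack([pred, true])

    def stat(fn):
        return bootstrap_ci(
            pairs, lambda m: fn(m[:, 0], m[:, 1]), n_boot=n_boot, seed=seed
        )

    rm, rm_lo, rm_hi = stat(rmse)
    r2, r2_lo, r2_hi = stat(r_squared)
    mp, mp_lo, mp_hi = stat(mape)
    return EvalReport(
        model=model,
        horizon=horizon,
        n_days=len(pred),
        rmse=rm,
        rmse_ci=(rm_lo, rm_hi),
        r2=r2,
        r2_ci=(r2_lo, r2_hi),
        mape=mp,
        mape_ci=(mp_lo, mp_hi),
        n_zero_truth_excluded=int((true == 0).sum()),
    )


def bootstrap_ci(
    per_day_values: np.ndarray,
    statistic,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Percentile bootstrap over days.

    Resamples rows (days) with replacement ``n_boot`` times, recomputes the
    statistic on each resample and returns
    ``(point, 2.5th percentile, 97.5th percentile)``.  Deterministic under
    ``seed``.
    """
    values = np.asarray(per_day_values)
    n = len(values)
    rng = np.random.default_rng(seed)
    point = float(statistic(values))
    reps = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            reps[i] = statistic(values[idx])
        except ValueError:  # e.g. all-zero truth in a MAPE resample
            reps[i] = np.nan
    lo, hi = np.nanpercentile(reps, [2.5, 97.5])
    return point, float(lo), float(hi)


def ci_difference_pvalue(
    est_a: float, ci_a: tuple, est_b: float, ci_b: tuple
) -> float:
    """Two-sided p value for a difference, reconstructed from 95% CIs.

    Each CI is converted to a standard error, SE = (upper - lower) / (2 *
    1.96); the difference is then tested with a Normal z statistic,
    assuming approximate normality of the metric's sampling distribution.
    """
    se_a = (ci_a[1] - ci_a[0]) / (2 * 1.959963984540054)
    se_b = (ci_b[1] - ci_b[0]) / (2 * 1.959963984540054)
    if se_a < 0 or se_b < 0:
        raise ValueError("invalid CI: upper < lower")
    se_diff = np.sqrt(se_a**2 + se_b**2)
    if se_diff == 0:
        if est_a == est_b:
            return 1.0
        log.warning("zero SE with unequal estimates; returning p=0")
        return 0.0
    z = (est_a - est_b) / se_diff
    return float(2.0 * stats.norm.sf(abs(z)))
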