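"""Synthetic daily platelet-demand and covariate generator.

Emulates the statistical structure of hospital platelet use: overdispersed
daily counts with a strong weekday profile (weekdays above weekends), a slow
multiplicative secular trend, and short-range autocorrelation carried by a
latent AR(1) process on the log rate.  Covariate columns come in two
flavours: *signal* features planted with a configurable correlation to
demand (census-, planned-surgery- and CBC-style), and *decoy* features that
are independent counts.

The default configuration is calibrated so that an 11-year series
(``n_days=4017``) has an overall mean of about 11.5 units/day with SD about
6.0, a daily range of roughly 0-39, and annual totals rising from roughly
2,600 in year 1 to 5,900 in year 11.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneratorConfig",
    "generate_demand_series",
    "generate_feature_columns",
    "generate_dataset",
    "DEFAULT_WEEKDAY_MULTIPLIERS",
]

#: Relative weekday levels, Sunday=0 .. Saturday=6, normalized to mean 1.
#: Weekends are quieter than weekdays, with a deep Sunday trough.
DEFAULT_WEEKDAY_MULTIPLIERS = (0.60, 1.08, 1.14, 1.16, 1.13, 1.16, 0.73)

#: Annual multiplicative growth matching a rise from ~2566 to ~5891
#: units/year across 11 calendar years: (5891/2566) ** (1/10).
DEFAULT_ANNUAL_TREND = float((5891.0 / 2566.0) ** 0.1)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic daily series.

    Attributes
    ----------
    n_days:
        Length of the series (>= 1).
    base_rate:
        Baseline demand rate in units/day before weekday, trend and AR
        modulation.
    weekday_multipliers:
        Seven positive multipliers indexed Sunday=0 .. Saturday=6.
    annual_trend:
        Multiplicative growth factor per year applied exponentially and
        centred so the series-average trend factor is ~1.
    ar_coefficient:
        AR(1) coefficient of the latent log-rate process, in [0, 1).
    latent_sigma:
        Stationary standard deviation of the latent log-rate process.
    dispersion:
        Negative-binomial shape k (gamma-mixed Poisson); the conditional
        variance is mu + mu**2 / k, so smaller k means more overdispersion.
    n_signal_features:
        Number of covariate columns planted with correlation to demand.
    signal_strengths:
        Target same-day Pearson correlation for each signal feature, each in
        (0, 1]; recycled if shorter than ``n_signal_features``.
    n_noise_features:
        Number of independent decoy count columns.
    seed:
        Seed that fully determines the output.
    start_date:
        Calendar date of the first row (ISO string).
    """

    n_days: int = 4017
    base_rate: float = 11.2
    weekday_multipliers: tuple = DEFAULT_WEEKDAY_MULTIPLIERS
    annual_trend: float = DEFAULT_ANNUAL_TREND
    ar_coefficient: float = 0.9
    latent_sigma: float = 0.18
    dispersion: float = 25.0
    n_signal_features: int = 6
    signal_strengths: tuple = (0.75, 0.65, 0.6, 0.55, 0.5, 0.5)
    n_noise_features: int = 12
    seed: int = 0
    start_date: str = "2008-01-01"

    def validate(self) -> None:
        if self.n_days < 1:
            raise ValueError(f"n_days must be >= 1, got {self.n_days}")
        if self.base_rate <= 0:
            raise ValueError("base_rate must be > 0")
        if len(self.weekday_multipliers) != 7:
            raise ValueError("weekday_multipliers must have length 7")
        if any(m <= 0 for m in self.weekday_multipliers):
            raise ValueError("weekday multipliers must be > 0")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must be in [0, 1)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.n_signal_features < 0 or self.n_noise_features < 0:
            raise ValueError("feature counts must be >= 0")
        if self.n_signal_features > 0:
            if not self.signal_strengths:
                raise ValueError("signal_strengths must be non-empty")
            if any(not 0.0 < s <= 1.0 for s in self.signal_strengths):
                raise ValueError("signal strengths must be in (0, 1]")


def _weekday_codes(dates: pd.DatetimeIndex) -> np.ndarray:
    """Day-of-week with Sunday=0 .. Saturday=6."""
    return (dates.dayofweek.to_numpy() + 1) % 7


def generate_demand_series(config: GeneratorConfig) -> pd.DataFrame:
    """Draw the daily demand series.

    The expected count on day i is
    ``base_rate * weekday_multiplier[d_w(i)] * trend(i) * exp(e_i)`` where
    ``e_i`` is a mean-corrected stationary AR(1) log-rate and counts are
    negative-binomial around that rate.  Deterministic under ``config.seed``.

    Returns a DataFrame with a ``date`` column (daily, contiguous) and an
    integer ``demand`` column.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_days
    dates = pd.date_range(config.start_date, periods=n, freq="D")
    dw = _weekday_codes(dates)

    # Exponential trend centred so its average factor over the span is ~1.
    t_years = (np.arange(n) - (n - 1) / 2.0) / 365.25
    trend = np.power(config.annual_trend, t_years)

    # Latent AR(1) on the log rate, stationary SD = latent_sigma,
    # mean-corrected so E[exp(e)] = 1.
    phi = config.ar_coefficient
    sig = config.latent_sigma
    e = np.zeros(n)
    if sig > 0:
        innov_sd = sig * np.sqrt(1.0 - phi**2)
        eps = rng.normal(0.0, innov_sd, size=n)
        e[0] = rng.normal(0.0, sig)
        for i in range(1, n):
            e[i] = phi * e[i - 1] + eps[i]
    latent = np.exp(e - sig**2 / 2.0)

    mult = np.asarray(config.weekday_multipliers, dtype=float)
    rate = config.base_rate * mult[dw] * trend * latent

    # Negative binomial as gamma-mixed Poisson with shape k = dispersion.
    k = config.dispersion
    lam = rng.gamma(shape=k, scale=rate / k)
    demand = rng.poisson(lam).astype(np.int64)
    return pd.DataFrame({"date": dates, "demand": demand})


def _count_transform(z: np.ndarray, loc: float, scale: float) -> np.ndarray:
    """Map a standardized series to a plausible non-negative count column."""
    return np.maximum(0, np.rint(loc + scale * z)).astype(np.int64)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd


def generate_feature_columns(
    demand: pd.DataFrame, config: GeneratorConfig
) -> pd.DataFrame:
    """Append planted-signal and decoy covariate columns.

    Signal features are noisy monotone transforms of demand targeting the
    configured same-day Pearson correlations.  Census- and planned-surgery-
    style columns are planted on same-day demand; CBC-style columns are
    planted on the standardized sum of same-day and next-day demand (low
    platelet counts lead transfusion), with the mixing weight calibrated so
    the same-day correlation still meets the target.  Decoy columns are
    independent negative-binomial counts.
    """
    config.validate()
    out = demand.copy()
    n = len(out)
    u = out["demand"].to_numpy(dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    # (prefix, base series builder). CBC bins carry next-day information.
    u_next = np.append(u[1:], u[-1])
    lead = u + u_next
    families = ("census", "surg_planned", "cbc")
    cbc_bins = ("lt5", "5_10", "10_20", "20_50", "50_70")

    strengths = list(config.signal_strengths)
    n_cbc = 0
    for j in range(config.n_signal_features):
        s = strengths[j % len(strengths)]
        fam = families[j % 3]
        if fam == "cbc":
            base, name = lead, f"cbc_{cbc_bins[n_cbc % len(cbc_bins)]}"
            n_cbc += 1
        else:
            base, name = u, f"{fam}_{j:02d}"
        if s >= 0.999:
            # Exact monotone linear transform of same-day demand.
            out[name] = (2 * out["demand"] + 3).astype(np.int64)
            continue
        z_base = _standardize(base)
        # Self-calibrate so corr(feature, same-day demand) ~= s even when
        # the base series mixes in next-day demand.
        c0 = float(np.corrcoef(z_base, _standardize(u))[0, 1]) if n > 2 else 1.0
        s_eff = min(0.999, s / max(c0, 1e-9))
        z = s_eff * z_base + np.sqrt(1.0 - s_eff**2) * rng.standard_normal(n)
        out[name] = _count_transform(z, loc=40.0, scale=12.0)

    for j in range(config.n_noise_features):
        fam = families[j % 3]
        suffix = f"noise_{j:02d}"
        name = f"{fam}_{suffix}"
        mu = rng.uniform(3.0, 60.0)
        lam = rng.gamma(shape=8.0, scale=mu / 8.0, size=n)
        out[name] = rng.poisson(lam).astype(np.int64)
    return out


def generate_dataset(config: GeneratorConfig) -> pd.DataFrame:
    """Full synthetic table: demand plus covariates, one row per day."""
    return generate_feature_columns(generate_demand_series(config), config)
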