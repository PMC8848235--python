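"""LSTM demand forecaster, implemented in pure NumPy.

Architecture: one long short-term memory layer over a lookback window of
daily feature vectors, a flatten step over all timestep outputs with a
configurable activation (ReLU or linear), dropout, and a dense output layer
with a single linear neuron — a small sequence-regression network.
Training uses Adam on mean squared error with analytic backpropagation
through time, L1-L2 regularization on the kernel weights, and early
stopping on a validation MSE.

Hyperparameters (batch size, LSTM units, dropout rate, L1/L2 penalties,
flatten activation) are tuned by randomized search over a fixed discrete
space, each draw scored by blocked cross-validation, matching the protocol
used for the linear model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from bloodstock.forecasting import _screened_features, blocked_cv_splits

__all__ = [
    "LstmConfig",
    "SEARCH_SPACE",
    "LSTMRegressor",
    "FittedLstm",
    "build_lstm",
    "fit_lstm",
    "lstm_factory",
]

log = logging.getLogger(__name__)

#: Discrete hyperparameter search space for the randomized grid search.
SEARCH_SPACE = {
    "batch_size": (50, 100),
    "lstm_units": (10, 50),
    "dropout_rate": tuple(round(0.05 * i, 2) for i in range(11)),  # 0 .. 0.50
    "l1_reg": (1e-9, 1e-7, 1e-5, 1e-3),
    "l2_reg": (1e-9, 1e-7, 1e-5, 1e-3),
    "flatten_activation": ("relu", "linear"),
}


@dataclass(frozen=True)
class LstmConfig:
    """One point in the hyperparameter space plus training/search setup.

    The first six fields must lie in :data:`SEARCH_SPACE`.  ``lookback_days``
    is the input sequence length (default one weekly cycle);
    ``n_random_draws`` is the randomized-search budget used by
    :func:`fit_lstm`.
    """

    batch_size: int = 50
    lstm_units: int = 10
    dropout_rate: float = 0.0
    l1_reg: float = 1e-9
    l2_reg: float = 1e-9
    flatten_activation: str = "linear"
    lookback_days: int = 7
    n_random_draws: int = 20
    seed: int = 0
    max_epochs: int = 200
    patience: int = 20
    learning_rate: float = 1e-3
    cv_folds: int = 5
    screen_r2: float | None = 0.2

    def __post_init__(self):
        for key in SEARCH_SPACE:
            value = getattr(self, key)
            if key in ("l1_reg", "l2_reg", "dropout_rate"):
                ok = any(np.isclose(value, v) for v in SEARCH_SPACE[key])
            else:
                ok = value in SEARCH_SPACE[key]
            if not ok:
                raise ValueError(
                    f"{key}={value!r} outside the search space {SEARCH_SPACE[key]}"
                )
        if self.lookback_days < 1:
            raise ValueError("lookback_days must be >= 1")
        if self.n_random_draws < 1:
            raise ValueError("n_random_draws must be >= 1")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class LSTMRegressor:
    """Single-layer LSTM -> flatten(+activation) -> dropout -> dense(1).

    Input shape (batch, lookback, n_features).  Weights follow the usual
    gate layout [input, forget, cell, output].  L1-L2 penalties apply to
    the LSTM kernel and the dense weights; dropout is applied to the
    flattened activations during training (inverted dropout).
    """

    def __init__(
        self,
        n_features: int,
        units: int,
        lookback: int,
        dropout: float = 0.0,
        l1: float = 0.0,
        l2: float = 0.0,
        activation: str = "linear",
        seed: int = 0,
    ):
        if activation not in ("relu", "linear"):
            raise ValueError(f"unknown activation {activation!r}")
        self.n_features, self.units, self.lookback = n_features, units, lookback
        self.dropout, self.l1, self.l2 = dropout, l1, l2
        self.activation = activation
        rng = np.random.default_rng(seed)
        F, U, T = n_features, units, lookback
        lim = np.sqrt(6.0 / (F + 4 * U))
        self.Wx = rng.uniform(-lim, lim, size=(F, 4 * U))
        # orthogonal recurrent init, block per gate
        self.Wh = np.concatenate(
            [np.linalg.qr(rng.standard_normal((U, U)))[0] for _ in range(4)],
            axis=1,
        )
        self.b = np.zeros(4 * U)
        self.b[U : 2 * U] = 1.0  # forget-gate bias
        lim_d = np.sqrt(6.0 / (T * U + 1))
        self.Wd = rng.uniform(-lim_d, lim_d, size=T * U)
        self.bd = 0.0
        self._rng = rng
        self._adam = None

    # ---- forward / backward -------------------------------------------------

    def param_count(self) -> int:
        """Trainable parameters: 4*(U*(F+U)+U) for the LSTM, T*U+1 dense."""
        F, U, T = self.n_features, self.units, self.lookback
        return 4 * (U * (F + U) + U) + T * U + 1

    def _forward(self, X, train=False):
        B, T, F = X.shape
        U = self.units
        h = np.zeros((B, U))
        c = np.zeros((B, U))
        cache = []
        H = np.empty((B, T, U))
        for t in range(T):
            z = X[:, t, :] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:, :U])
            f = _sigmoid(z[:, U : 2 * U])
            g = np.tanh(z[:, 2 * U : 3 * U])
            o = _sigmoid(z[:, 3 * U :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            H[:, t, :] = h
            cache.append((X[:, t, :], i, f, g, o, c_prev, tc))
        A = H.reshape(B, T * U)
        if self.activation == "relu":
            act_mask = A > 0
            A = A * act_mask
        else:
            act_mask = None
        if train and self.dropout > 0:
            drop = (self._rng.random(A.shape) >= self.dropout) / (
                1.0 - self.dropout
            )
            A = A * drop
        else:
            drop = None
        yhat = A @ self.Wd + self.bd
        return yhat, (cache, A, act_mask, drop, H)

    def _backward(self, X, y, yhat, ctx):
        cache, A, act_mask, drop, H = ctx
        B, T, F = X.shape
        U = self.units
        dy = 2.0 * (yhat - y) / B
        gWd = A.T @ dy + self.l1 * np.sign(self.Wd) + 2 * self.l2 * self.Wd
        gbd = dy.sum()
        dA = np.outer(dy, self.Wd)
        if drop is not None:
            dA = dA * drop
        if act_mask is not None:
            dA = dA * act_mask
        dH = dA.reshape(B, T, U)

        gWx = self.l1 * np.sign(self.Wx) + 2 * self.l2 * self.Wx
        gWh = np.zeros_like(self.Wh)
        gb = np.zeros_like(self.b)
        dh_next = np.zeros((B, U))
        dc_next = np.zeros((B, U))
        h_prev_list = [np.zeros((B, U))] + [H[:, t, :] for t in range(T - 1)]
        for t in reversed(range(T)):
            x_t, i, f, g, o, c_prev, tc = cache[t]
            dh = dH[:, t, :] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1 - tc**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            gWx += x_t.T @ dz
            gWh += h_prev_list[t].T @ dz
            gb += dz.sum(axis=0)
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
        return gWx, gWh, gb, gWd, gbd

    def loss(self, X, y) -> float:
        yhat, _ = self._forward(X, train=False)
        reg = self.l1 * (np.abs(self.Wx).sum() + np.abs(self.Wd).sum()) + self.l2 * (
            (self.Wx**2).sum() + (self.Wd**2).sum()
        )
        return float(np.mean((yhat - y) ** 2) + reg)

    # ---- training -----------------------------------------------------------

    def _adam_step(self, grads, lr, t):
        params = ["Wx", "Wh", "b", "Wd", "bd"]
        if self._adam is None:
            self._adam = {
                p: [
                    np.zeros_like(np.asarray(getattr(self, p), dtype=float)),
                    np.zeros_like(np.asarray(getattr(self, p), dtype=float)),
                ]
                for p in params
            }
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g in zip(params, grads):
            m, v = self._adam[p]
            m[...] = b1 * m + (1 - b1) * np.asarray(g)
            v[...] = b2 * v + (1 - b2) * np.asarray(g) ** 2
            mhat = m / (1 - b1**t)
            vhat = v / (1 - b2**t)
            update = lr * mhat / (np.sqrt(vhat) + eps)
            if p == "bd":
                self.bd -= float(update)
            else:
                setattr(self, p, getattr(self, p) - update)

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
        batch_size: int = 50,
        max_epochs: int = 200,
        patience: int = 20,
        learning_rate: float = 1e-3,
    ) -> "LSTMRegressor":
        """Adam / MSE training with early stopping on validation loss.

        Without a validation set, trains for ``max_epochs`` epochs.  Batches
        preserve temporal order (no shuffling across epochs is needed for
        this data size and keeps runs bit-reproducible).
        """
        n = len(X)
        best_val = np.inf
        best_weights = None
        strikes = 0
        step = 0
        for epoch in range(max_epochs):
            for lo in range(0, n, batch_size):
                xb, yb = X[lo : lo + batch_size], y[lo : lo + batch_size]
                yhat, ctx = self._forward(xb, train=True)
                if not np.all(np.isfinite(yhat)):
                    raise FloatingPointError("training diverged")
                grads = self._backward(xb, yb, yhat, ctx)
                step += 1
                self._adam_step(grads, learning_rate, step)
            if X_val is not None and len(X_val):
                val = float(np.mean((self.predict_raw(X_val) - y_val) ** 2))
                if val < best_val - 1e-12:
                    best_val = val
                    best_weights = (
                        self.Wx.copy(),
                        self.Wh.copy(),
                        self.b.copy(),
                        self.Wd.copy(),
                        self.bd,
                    )
                    strikes = 0
                else:
                    strikes += 1
                    if strikes >= patience:
                        break
        if best_weights is not None:
            self.Wx, self.Wh, self.b, self.Wd, self.bd = (
                best_weights[0],
                best_weights[1],
                best_weights[2],
                best_weights[3],
                best_weights[4],
            )
        return self

    def predict_raw(self, X: np.ndarray) -> np.ndarray:
        yhat, _ = self._forward(X, train=False)
        return yhat


def build_lstm(config: LstmConfig, n_features: int) -> LSTMRegressor:
    """Instantiate the (untrained) network for a given feature width."""
    return LSTMRegressor(
        n_features=n_features,
        units=config.lstm_units,
        lookback=config.lookback_days,
        dropout=config.dropout_rate,
        l1=config.l1_reg,
        l2=config.l2_reg,
        activation=config.flatten_activation,
        seed=config.seed,
    )


# ---- fitting on the design matrix -------------------------------------------


def _make_sequences(F: np.ndarray, y: np.ndarray, lookback: int):
    """Sequence i holds feature rows i-lookback+1 .. i, labelled y[i]."""
    n = len(F)
    idx = np.arange(lookback - 1, n)
    X = np.stack([F[i - lookback + 1 : i + 1] for i in idx])
    return X, y[idx], idx


@dataclass
class FittedLstm:
    """Trained network plus the scaling and context needed to forecast.

    ``predict`` expects a window of rows immediately following the training
    span; the tail of the training features supplies lookback context for
    the first days of the window.
    """

    kind: str
    net: LSTMRegressor
    features: list
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    tail: np.ndarray
    config: LstmConfig
    target: str

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        F = (df[self.features].to_numpy(dtype=float) - self.x_mean) / self.x_sd
        full = np.vstack([self.tail, F])
        lb = self.config.lookback_days
        X = np.stack(
            [full[i : i + lb] for i in range(len(F))]
        )  # tail has lb-1 rows, so sequence i ends at window row i
        z = self.net.predict_raw(X)
        return np.clip(z * self.y_sd + self.y_mean, 0.0, None)


def _draw_hyperparams(rng) -> dict:
    return {k: v[rng.integers(len(v))] for k, v in SEARCH_SPACE.items()}


def fit_lstm(
    train: pd.DataFrame, target: str, config: LstmConfig = LstmConfig()
) -> FittedLstm:
    """Randomized hyperparameter search + final refit on one training span.

    Draws ``config.n_random_draws`` combinations uniformly from
    :data:`SEARCH_SPACE`, scores each by blocked CV on MSE (the CV
    validation block doubles as the early-stopping monitor), then refits
    the best on the full span.  Features and target are standardized on the
    training span; a draw whose training diverges is discarded with a
    warning.  Deterministic given ``config.seed`` and the training span.
    """
    feats = _screened_features(train, config.screen_r2)
    if not feats:
        raise ValueError("no features survive screening")
    F_raw = train[feats].to_numpy(dtype=float)
    y_raw = train[target].to_numpy(dtype=float)
    x_mean, x_sd = F_raw.mean(axis=0), F_raw.std(axis=0)
    x_sd = np.where(x_sd == 0, 1.0, x_sd)
    y_mean, y_sd = float(y_raw.mean()), float(y_raw.std()) or 1.0
    F = (F_raw - x_mean) / x_sd
    y = (y_raw - y_mean) / y_sd

    lb = config.lookback_days
    X, yy, _ = _make_sequences(F, y, lb)
    ss = np.random.SeedSequence([config.seed, len(train), {"y2": 2, "y4": 4}.get(target, 0)])
    rng = np.random.default_rng(ss)

    draws = [_draw_hyperparams(rng) for _ in range(config.n_random_draws)]
    seeds = rng.integers(0, 2**31 - 1, size=config.n_random_draws + 1)

    best_score, best_hp = np.inf, draws[0]
    if config.n_random_draws > 1:
        splits = blocked_cv_splits(len(X), config.cv_folds)
        for d, hp in enumerate(draws):
            score = 0.0
            try:
                for tr, va in splits:
                    net = LSTMRegressor(
                        len(feats), hp["lstm_units"], lb,
                        dropout=hp["dropout_rate"], l1=hp["l1_reg"],
                        l2=hp["l2_reg"], activation=hp["flatten_activation"],
                        seed=int(seeds[d]),
                    )
                    net.fit(
                        X[tr], yy[tr], X[va], yy[va],
                        batch_size=hp["batch_size"],
                        max_epochs=config.max_epochs,
                        patience=config.patience,
                        learning_rate=config.learning_rate,
                    )
                    score += float(np.mean((net.predict_raw(X[va]) - yy[va]) ** 2))
            except FloatingPointError:
                log.warning("discarding diverged hyperparameter draw %r", hp)
                continue
            if score < best_score:
                best_score, best_hp = score, hp

    # final refit on the full span; last 10% of sequences monitor stopping
    n_val = max(1, len(X) // 10)
    net = LSTMRegressor(
        len(feats), best_hp["lstm_units"], lb,
        dropout=best_hp["dropout_rate"], l1=best_hp["l1_reg"],
        l2=best_hp["l2_reg"], activation=best_hp["flatten_activation"],
        seed=int(seeds[-1]),
    )
    net.fit(
        X[:-n_val], yy[:-n_val], X[-n_val:], yy[-n_val:],
        batch_size=best_hp["batch_size"],
        max_epochs=config.max_epochs,
        patience=config.patience,
        learning_rate=config.learning_rate,
    )
    chosen = replace(
        config,
        batch_size=int(best_hp["batch_size"]),
        lstm_units=int(best_hp["lstm_units"]),
        dropout_rate=float(best_hp["dropout_rate"]),
        l1_reg=float(best_hp["l1_reg"]),
        l2_reg=float(best_hp["l2_reg"]),
        flatten_activation=best_hp["flatten_activation"],
    )
    return FittedLstm(
        kind="lstm",
        net=net,
        features=feats,
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        y_sd=y_sd,
        tail=F[-(lb - 1) :] if lb > 1 else np.empty((0, len(feats))),
        config=chosen,
        target=target,
    )


def lstm_factory(config: LstmConfig = LstmConfig()):
    """Adapter for :func:`bloodstock.forecasting.rolling_origin_forecast`."""

    def factory(train: pd.DataFrame, target: str) -> FittedLstm:
        return fit_lstm(train, target, config)

    return factory
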