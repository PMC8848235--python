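"""Shelf-life-aware blood-bank inventory simulator.

Platelet concentrates have a remaining shelf life of 4 days once they enter
stock, so stock is tracked in four age strata ``r0..r3`` (``rx`` holds the
units that expire at the end of day ``i + x``).  Production orders placed on
day i arrive at the start of day i+2 with the full 4-day shelf life; donors
are only activated Monday-Friday, so no orders are placed on Fridays or
Saturdays and, consequently, nothing arrives on Sundays or Mondays.

Each simulated day runs through a fixed stepwise calculation:

1. *init* — age the stock one day (``r0<-r1, r1<-r2, r2<-r3``), receive the
   order placed two days ago into ``r3``, reset purchases and waste to 0.
2. *consume* — transfuse the day's demand ``u`` oldest-first (FIFO through
   ``r0 -> r1 -> r2 -> r3``), tracking running balances ``t1..t4``;
   ``t4 = total stock - u`` may be transiently negative.
3. *purchase* — if ``t4 <= beta``, buy ``b = max(0, gamma - t4)`` units
   externally (an *emergency purchase* at roughly double cost); purchased
   units first cover the deficit, any surplus enters stock fresh at ``r3``.
4. *expire* — unconsumed ``r0`` units are discarded as waste ``w``.
5. *close* — end-of-day stock ``s = r1 + r2 + r3``.

The ordering strategy restores an end-of-day stock target ``alpha`` on top
of the predicted demand over the order's coverage window: 2 days ahead for
orders placed Sunday-Wednesday, 4 days ahead for Thursday orders (which must
also cover the orderless Friday-Saturday gap):

    o_i = round(max(0, p + alpha - s_i - o_{i-1}))

where ``p`` is the 2- or 4-day demand forecast and ``o_{i-1}`` is already in
the pipeline, arriving tomorrow.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PolicyParams",
    "InventoryState",
    "DayLedgerEntry",
    "SimulationLedger",
    "order_quantity",
    "step_day",
    "run_simulation",
    "run_constant_order_simulation",
    "weekday_code",
]


def weekday_code(date) -> int:
    """Day of week with Sunday=0 .. Saturday=6."""
    return (pd.Timestamp(date).dayofweek + 1) % 7


@dataclass(frozen=True)
class PolicyParams:
    """The three inventory control parameters (platelet units).

    alpha: target end-of-day stock the ordering strategy restores.
    beta:  purchase trigger — an emergency purchase fires when the
           post-consumption balance falls to or below beta.
    gamma: stock target right after an emergency purchase.
    """

    alpha: int
    beta: int = 0
    gamma: int = 0


@dataclass
class InventoryState:
    """Age-stratified stock plus the order pipeline.

    ``r0..r3`` count units by remaining shelf life (r0 expires at the end of
    the current day).  ``order_minus_1``/``order_minus_2`` are the units
    ordered one and two days ago; the latter arrive today.
    """

    r0: int = 0
    r1: int = 0
    r2: int = 0
    r3: int = 0
    order_minus_1: int = 0
    order_minus_2: int = 0

    @property
    def stock(self) -> int:
        return self.r0 + self.r1 + self.r2 + self.r3


@dataclass(frozen=True)
class DayLedgerEntry:
    date: object
    weekday: int
    demand: int
    order: int
    arrival: int
    purchase: int
    waste: int
    stock: int
    t4: int


@dataclass
class SimulationLedger:
    """Per-day records with horizon totals, rates and cost.

    ``waste_rate`` and ``shortage_rate`` are expressed relative to the
    number of units transfused over the (post-warm-up) horizon.
    """

    entries: list = field(default_factory=list)
    warmup: int = 0

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.entries])

    def _post_warmup(self):
        return self.entries[self.warmup :]

    @property
    def total_used(self) -> int:
        return sum(e.demand for e in self._post_warmup())

    @property
    def total_ordered(self) -> int:
        return sum(e.order for e in self._post_warmup())

    @property
    def total_purchased(self) -> int:
        return sum(e.purchase for e in self._post_warmup())

    @property
    def total_wasted(self) -> int:
        return sum(e.waste for e in self._post_warmup())

    @property
    def waste_rate(self) -> float:
        used = self.total_used
        return self.total_wasted / used if used else float("nan")

    @property
    def shortage_rate(self) -> float:
        used = self.total_used
        return self.total_purchased / used if used else float("nan")

    def summary(self) -> dict:
        return {
            "days": len(self._post_warmup()),
            "total_used": self.total_used,
            "total_ordered": self.total_ordered,
            "total_purchased": self.total_purchased,
            "total_wasted": self.total_wasted,
            "waste_rate": self.waste_rate,
            "shortage_rate": self.shortage_rate,
        }


def order_quantity(
    state: InventoryState,
    p2: float,
    p4: float,
    alpha: int,
    weekday: int,
) -> int:
    """Units to order at the end of the day under the stock-target policy.

    Sunday-Wednesday orders cover the next 2 days (forecast ``p2``);
    Thursday orders cover 4 days (``p4``) because no orders are possible on
    Fridays and Saturdays; Friday/Saturday return 0.  The current end-of-day
    stock and yesterday's order (arriving tomorrow) are netted out so
    pipeline inventory is not double-ordered; the result is rounded half-up
    and clamped at 0.
    """
    if not 0 <= weekday <= 6:
        raise ValueError(f"weekday must be in 0..6, got {weekday}")
    if p2 < 0 or p4 < 0:
        raise ValueError("forecasts must be non-negative")
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if weekday in (5, 6):  # Friday, Saturday: donors cannot be activated
        return 0
    p = p4 if weekday == 4 else p2
    raw = p + alpha - state.stock - state.order_minus_1
    if raw <= 0:
        return 0
    return int(np.floor(raw + 0.5))


def step_day(
    state: InventoryState, u: int, beta: int, gamma: int
) -> tuple[InventoryState, DayLedgerEntry]:
    """Advance the inventory by one day of demand ``u``.

    Returns the end-of-day state (order pipeline untouched — ordering is a
    separate decision) and a ledger fragment with arrival, purchase, waste,
    end-of-day stock and the post-consumption balance t4.  All arithmetic is
    integer; intermediate balances may be negative but the returned state is
    non-negative by construction.
    """
    if u < 0:
        raise ValueError("demand must be non-negative")
    # (1) init: age stock, receive the order placed two days ago.
    r0, r1, r2, r3 = state.r1, state.r2, state.r3, state.order_minus_2
    arrival = state.order_minus_2
    b = 0

    # (2) consume oldest-first; t1..t4 are cumulative running balances, so
    # t4 always equals total stock minus demand (negative on a shortfall).
    t1 = r0 - u
    t2 = r1 + t1
    t3 = r2 + t2
    t4 = r3 + t3
    # post-consumption stratum contents under FIFO issuance
    r0 = max(t1, 0)
    r1 = min(r1, max(t2, 0))
    r2 = min(r2, max(t3, 0))
    r3 = min(r3, max(t4, 0))
    deficit = max(0, -t4)

    # (3) emergency purchase when the balance falls to or below beta.
    if t4 <= beta:
        b = max(0, gamma - t4)
        surplus = b - deficit  # units left after covering any shortfall
        if surplus > 0:
            r3 += surplus  # purchased units enter stock fresh

    # (4) unconsumed units with zero remaining shelf life expire.
    w = r0

    # (5) end-of-day stock.
    s = r1 + r2 + r3
    new_state = InventoryState(
        r0=0,
        r1=r1,
        r2=r2,
        r3=r3,
        order_minus_1=state.order_minus_1,
        order_minus_2=state.order_minus_2,
    )
    entry = DayLedgerEntry(
        date=None,
        weekday=-1,
        demand=u,
        order=0,
        arrival=arrival,
        purchase=b,
        waste=w,
        stock=s,
        t4=t4,
    )
    return new_state, entry


def _simulate(
    demand: pd.DataFrame,
    order_fn,
    beta: int,
    gamma: int,
    warmup: int,
) -> SimulationLedger:
    dates = pd.to_datetime(demand["date"]).to_numpy()
    u = demand["demand"].to_numpy(dtype=np.int64)
    state = InventoryState()
    ledger = SimulationLedger(warmup=warmup)
    for i in range(len(u)):
        dw = weekday_code(dates[i])
        state, entry = step_day(state, int(u[i]), beta, gamma)
        o = order_fn(i, state, dw)
        state.order_minus_2 = state.order_minus_1
        state.order_minus_1 = o
        ledger.entries.append(replace(entry, date=dates[i], weekday=dw, order=o))
    return ledger


def run_simulation(
    demand: pd.DataFrame,
    forecasts: pd.DataFrame,
    params: PolicyParams,
    warmup: int = 14,
) -> SimulationLedger:
    """Simulate the inventory over the days covered by ``forecasts``.

    ``demand`` supplies the actual transfusions ``u_i``; ``forecasts`` must
    hold columns ``date``, ``p2``, ``p4`` for every simulated day.  The
    simulation starts with empty stock, so the first ``warmup`` days are
    excluded from the ledger totals.
    """
    f = forecasts.reset_index(drop=True)
    d = demand.reset_index(drop=True)
    merged = d.merge(f[["date", "p2", "p4"]], on="date", how="inner")
    if len(merged) != len(f):
        raise ValueError(
            "forecast dates do not align with demand dates "
            f"({len(merged)} of {len(f)} matched)"
        )
    p2 = merged["p2"].to_numpy(dtype=float)
    p4 = merged["p4"].to_numpy(dtype=float)

    def order_fn(i, state, dw):
        return order_quantity(state, p2[i], p4[i], params.alpha, dw)

    return _simulate(merged, order_fn, params.beta, params.gamma, warmup)


def run_constant_order_simulation(
    demand: pd.DataFrame,
    daily_order: int,
    beta: int = 0,
    gamma: int = 0,
    warmup: int = 14,
) -> SimulationLedger:
    """Baseline: order a fixed quantity on every order-capable day.

    Stands in for a historical, non-forecasting ordering practice: the same
    ``daily_order`` units are ordered every Sunday-Thursday regardless of
    stock or forecasts; emergency purchases still cover any shortfall.
    """
    if daily_order < 0:
        raise ValueError("daily_order must be non-negative")

    def order_fn(i, state, dw):
        return 0 if dw in (5, 6) else daily_order

    return _simulate(
        demand.reset_index(drop=True), order_fn, beta, gamma, warmup
    )
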