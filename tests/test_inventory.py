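"""Inventory simulator: worked example, FIFO semantics, conservation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bloodstock.inventory import (
    InventoryState,
    PolicyParams,
    order_quantity,
    run_constant_order_simulation,
    run_simulation,
    step_day,
    weekday_code,
)
from conftest import make_daily_table


# ---- ordering strategy -------------------------------------------------------


@pytest.mark.parametrize("weekday", [5, 6])
def test_no_orders_on_friday_or_saturday(weekday):
    state = InventoryState(r1=1, r2=2, order_minus_1=4)
    assert order_quantity(state, 50.0, 90.0, alpha=13, weekday=weekday) == 0


def test_midweek_order_arithmetic():
    # alpha=13, stock 10, yesterday's order 5, p2=20 -> 13+20-10-5 = 18
    state = InventoryState(r1=4, r2=3, r3=3, order_minus_1=5)
    assert order_quantity(state, 20.0, 0.0, alpha=13, weekday=2) == 18


def test_thursday_uses_four_day_forecast():
    state = InventoryState(r1=2, order_minus_1=1)
    assert order_quantity(state, 5.0, 11.0, alpha=3, weekday=4) == 11


def test_order_clamped_at_zero():
    state = InventoryState(r3=40)
    assert order_quantity(state, 0.0, 10.0, alpha=0, weekday=4) == 0


def test_order_rounds_half_up():
    state = InventoryState()
    assert order_quantity(state, 2.5, 0.0, alpha=0, weekday=1) == 3


def test_order_rejects_negative_forecast():
    with pytest.raises(ValueError):
        order_quantity(InventoryState(), -1.0, 0.0, 0, 1)


# ---- daily step --------------------------------------------------------------


def test_worked_emergency_purchase_example():
    """Stock 2, unexpected demand 4, beta=gamma=0: t4 = -2, 2 units bought,
    end-of-day stock 0."""
    state = InventoryState(r1=2)
    new, entry = step_day(state, u=4, beta=0, gamma=0)
    assert entry.t4 == -2
    assert entry.purchase == 2
    assert entry.stock == 0
    assert new.stock == 0


def test_expiring_units_become_waste():
    # r1=3 ages to r0; with no demand all 3 expire
    state = InventoryState(r1=3, r2=1)
    new, entry = step_day(state, u=0, beta=0, gamma=0)
    assert entry.waste == 3
    assert entry.stock == 1
    assert new.r1 == 1 and new.r2 == 0 and new.r3 == 0


def test_fifo_consumes_oldest_first():
    # after aging: r0=1, r1=2; demand 2 takes the r0 unit then one r1 unit
    state = InventoryState(r1=1, r2=2)
    new, entry = step_day(state, u=2, beta=0, gamma=0)
    assert entry.waste == 0
    assert entry.stock == 1
    assert new.r1 == 1


def test_arrivals_enter_freshest_stratum():
    state = InventoryState(order_minus_2=5)
    new, entry = step_day(state, u=0, beta=0, gamma=0)
    assert entry.arrival == 5
    assert new.r3 == 5 and new.stock == 5


def test_purchase_surplus_enters_stock_when_gamma_positive():
    state = InventoryState(r1=1)
    new, entry = step_day(state, u=3, beta=0, gamma=4)
    # t4 = -2: purchase covers the 2-unit deficit and restocks to gamma
    assert entry.purchase == 6
    assert entry.stock == 4 and new.r3 == 4


def test_purchase_never_negative():
    # 0 <= t4 <= beta but gamma < t4: nothing to buy
    state = InventoryState(r2=2)
    new, entry = step_day(state, u=0, beta=5, gamma=1)
    assert entry.purchase == 0


# ---- whole-horizon simulations ----------------------------------------------


def _forecasts_for(demand, p2, p4, model="stub"):
    f = demand[["date"]].copy()
    f["p2"], f["p4"], f["model"] = p2, p4, model
    return f


def test_zero_demand_zero_alpha_is_fixed_point():
    d = make_daily_table(np.zeros(60, dtype=int))
    f = _forecasts_for(d, 0.0, 0.0)
    ledger = run_simulation(d, f, PolicyParams(alpha=0), warmup=0)
    assert ledger.total_ordered == 0
    assert ledger.total_purchased == 0
    assert ledger.total_wasted == 0


def test_all_zero_forecasts_force_pure_emergency_supply():
    rng = np.random.default_rng(4)
    d = make_daily_table(rng.poisson(8, 60))
    f = _forecasts_for(d, 0.0, 0.0)
    ledger = run_simulation(d, f, PolicyParams(alpha=0), warmup=0)
    assert ledger.shortage_rate == pytest.approx(1.0)
    assert ledger.waste_rate == 0.0


def test_forecast_misalignment_rejected():
    d = make_daily_table(np.ones(30, dtype=int))
    f = _forecasts_for(d, 10.0, 20.0).iloc[:20]
    f = f.copy()
    f.loc[0, "date"] = f.loc[0, "date"] - pd.Timedelta(days=400)
    with pytest.raises(ValueError, match="align"):
        run_simulation(d, f, PolicyParams(alpha=5))


def test_no_arrivals_on_sundays_or_mondays():
    rng = np.random.default_rng(9)
    d = make_daily_table(rng.poisson(11, 200))
    f = _forecasts_for(d, 23.0, 46.0)
    ledger = run_simulation(d, f, PolicyParams(alpha=13), warmup=0)
    frame = ledger.frame()
    assert frame.loc[frame["weekday"].isin([0, 1]), "arrival"].sum() == 0
    assert frame.loc[frame["weekday"].isin([2, 3, 4, 5, 6]), "arrival"].sum() > 0


# ---- unit-level FIFO oracle --------------------------------------------------


def _unit_level_oracle(demand_df, p2, p4, alpha, beta, gamma):
    """Independent reference: every platelet unit tracked individually by
    its expiry day; returns per-day (order, arrival, purchase, waste, stock).
    """
    units = []  # expiry day indices, unconsumed stock
    pending = {}  # arrival day -> quantity
    rows = []
    dates = pd.to_datetime(demand_df["date"]).tolist()
    u_series = demand_df["demand"].tolist()
    for i, (date, u) in enumerate(zip(dates, u_series)):
        dw = weekday_code(date)
        arrival = pending.pop(i, 0)
        units.extend([i + 3] * arrival)  # fresh units live through day i+3
        units.sort()
        # consume oldest first
        served = 0
        while served < u and units:
            units.pop(0)
            served += 1
        t4 = len(units) - (u - served)
        purchase = 0
        if t4 <= beta:
            purchase = max(0, gamma - t4)
            direct = min(purchase, u - served)
            surplus = purchase - direct
            units.extend([i + 3] * surplus)
            units.sort()
        waste = sum(1 for e in units if e <= i)
        units = [e for e in units if e > i]
        stock = len(units)
        order = 0
        if dw not in (5, 6):
            p = p4[i] if dw == 4 else p2[i]
            prev_order = pending.get(i + 1, 0)
            order = max(0, int(np.floor(p + alpha - stock - prev_order + 0.5)))
            pending[i + 2] = order
        rows.append((order, arrival, purchase, waste, stock))
    return rows


@pytest.mark.parametrize("seed", range(6))
def test_ledger_matches_unit_level_oracle(seed):
    """100-day random instances: the stratified simulator and an
    independent per-unit FIFO tracker produce identical ledgers."""
    rng = np.random.default_rng(seed)
    d = make_daily_table(rng.poisson(11, 100))
    p2 = rng.uniform(0, 40, 100)
    p4 = rng.uniform(0, 80, 100)
    alpha, beta, gamma = rng.integers(0, 20), rng.integers(0, 4), rng.integers(0, 6)
    f = d[["date"]].copy()
    f["p2"], f["p4"] = p2, p4
    ledger = run_simulation(d, f, PolicyParams(int(alpha), int(beta), int(gamma)),
                            warmup=0)
    oracle = _unit_level_oracle(d, p2, p4, int(alpha), int(beta), int(gamma))
    for entry, (o, a, b, w, s) in zip(ledger.entries, oracle):
        assert (entry.order, entry.arrival, entry.purchase,
                entry.waste, entry.stock) == (o, a, b, w, s)


def _conservation_gap(ledger):
    """Arrivals + purchases-entering-stock - consumed-from-stock - waste
    minus the stock change; zero iff every unit is accounted for."""
    stock_prev = 0
    gap = 0
    for e in ledger.entries:
        deficit = max(0, -e.t4)
        entered = e.purchase - min(e.purchase, deficit)
        consumed_from_stock = e.demand - min(deficit, e.purchase)
        gap += e.arrival + entered - consumed_from_stock - e.waste - (
            e.stock - stock_prev
        )
        stock_prev = e.stock
    return gap


@pytest.mark.parametrize("seed", range(10))
def test_conservation_identity_on_random_instances(seed):
    rng = np.random.default_rng(100 + seed)
    d = make_daily_table(rng.poisson(11, 200))
    f = d[["date"]].copy()
    f["p2"] = rng.uniform(0, 40, 200)
    f["p4"] = rng.uniform(0, 80, 200)
    params = PolicyParams(int(rng.integers(0, 25)), int(rng.integers(0, 4)),
                          int(rng.integers(0, 6)))
    ledger = run_simulation(d, f, params, warmup=0)
    assert _conservation_gap(ledger) == 0


def test_beta_gamma_zero_purchases_equal_daily_deficit():
    """With beta=gamma=0 a purchase happens exactly when demand exceeds
    stock, and covers exactly the deficit."""
    rng = np.random.default_rng(42)
    d = make_daily_table(rng.poisson(11, 150))
    f = d[["date"]].copy()
    f["p2"] = rng.uniform(10, 30, 150)
    f["p4"] = rng.uniform(20, 60, 150)
    ledger = run_simulation(d, f, PolicyParams(alpha=3), warmup=0)
    for e in ledger.entries:
        assert e.purchase == max(0, -e.t4)


def test_homogeneity_under_integer_scaling():
    """Scaling demand, (integer) forecasts and alpha/beta/gamma by k scales
    all ledger totals by exactly k."""
    rng = np.random.default_rng(7)
    demand = rng.poisson(11, 120)
    p2 = rng.integers(0, 40, 120)
    p4 = rng.integers(0, 80, 120)
    k = 3
    totals = []
    for scale in (1, k):
        d = make_daily_table(demand * scale)
        f = d[["date"]].copy()
        f["p2"], f["p4"] = p2 * scale, p4 * scale
        params = PolicyParams(5 * scale, 1 * scale, 2 * scale)
        ledger = run_simulation(d, f, params, warmup=0)
        totals.append(
            (ledger.total_ordered, ledger.total_purchased, ledger.total_wasted)
        )
    assert totals[1] == tuple(k * t for t in totals[0])


@given(
    seed=st.integers(0, 10**6),
    alpha=st.integers(0, 30),
    beta=st.integers(0, 10),
    gamma=st.integers(0, 10),
)
@settings(max_examples=25, deadline=None)
def test_state_and_ledger_nonnegative(seed, alpha, beta, gamma):
    rng = np.random.default_rng(seed)
    d = make_daily_table(rng.poisson(11, 60))
    f = d[["date"]].copy()
    f["p2"] = rng.uniform(0, 40, 60)
    f["p4"] = rng.uniform(0, 80, 60)
    ledger = run_simulation(d, f, PolicyParams(alpha, beta, gamma), warmup=0)
    for e in ledger.entries:
        assert min(e.order, e.arrival, e.purchase, e.waste, e.stock) >= 0


def test_constant_order_baseline_orders_only_sun_thu():
    rng = np.random.default_rng(3)
    d = make_daily_table(rng.poisson(11, 100))
    ledger = run_constant_order_simulation(d, daily_order=16, warmup=0)
    frame = ledger.frame()
    assert (frame.loc[frame["weekday"].isin([5, 6]), "order"] == 0).all()
    assert (frame.loc[~frame["weekday"].isin([5, 6]), "order"] == 16).all()
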