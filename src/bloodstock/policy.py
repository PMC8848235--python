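"""Cost model and exhaustive search over the inventory control parameters.

The cost of a run charges every wasted unit at the local production price
and every emergency purchase at roughly double that price (rounded up, to
also penalize the transfusion delay a purchase implies):

    c = unit_cost * total_waste + emergency_cost * total_purchases

The three control parameters (alpha, beta, gamma) are chosen by exhaustive
grid search over 0..30 in steps of 1, minimizing c over a simulated horizon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from bloodstock.inventory import PolicyParams, SimulationLedger, run_simulation

__all__ = ["CostConfig", "total_cost", "grid_search"]


@dataclass(frozen=True)
class CostConfig:
    """Unit economics (US dollars per platelet unit)."""

    unit_cost: float = 350.0
    emergency_cost: float = 700.0

    def __post_init__(self):
        if self.emergency_cost < self.unit_cost:
            raise ValueError("emergency_cost must be >= unit_cost")


def total_cost(ledger: SimulationLedger, config: CostConfig = CostConfig()) -> float:
    """Total cost of a simulated horizon: waste at production price,
    emergency purchases at the emergency price."""
    return (
        config.unit_cost * ledger.total_wasted
        + config.emergency_cost * ledger.total_purchased
    )


def grid_search(
    demand: pd.DataFrame,
    forecasts: pd.DataFrame,
    alpha_range: Sequence[int] = range(31),
    beta_range: Sequence[int] = range(31),
    gamma_range: Sequence[int] = range(31),
    cost_config: CostConfig = CostConfig(),
    warmup: int = 14,
) -> tuple[PolicyParams, pd.DataFrame]:
    """Exhaustively evaluate every (alpha, beta, gamma) triple.

    Runs one inventory simulation per triple and returns the
    cost-minimizing parameters (ties broken by smallest alpha, then beta,
    then gamma) together with the full cost surface as a DataFrame with
    columns ``alpha, beta, gamma, cost, waste_rate, shortage_rate``.
    """
    alpha_range = list(alpha_range)
    beta_range = list(beta_range)
    gamma_range = list(gamma_range)
    if not alpha_range or not beta_range or not gamma_range:
        raise ValueError("parameter ranges must be non-empty")

    rows = []
    best = None
    for a in alpha_range:
        for b in beta_range:
            for g in gamma_range:
                ledger = run_simulation(
                    demand, forecasts, PolicyParams(a, b, g), warmup=warmup
                )
                c = total_cost(ledger, cost_config)
                rows.append(
                    {
                        "alpha": a,
                        "beta": b,
                        "gamma": g,
                        "cost": c,
                        "waste_rate": ledger.waste_rate,
                        "shortage_rate": ledger.shortage_rate,
                    }
                )
                key = (c, a, b, g)
                if best is None or key < best:
                    best = key
    c, a, b, g = best
    return PolicyParams(a, b, g), pd.DataFrame(rows)
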