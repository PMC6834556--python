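"""Fixed-price annual profit comparison for a single farm.

A small producer (default 12,000 slaughtered pigs/year) is a price taker:
the meat price stays fixed across regimes and the comparison is driven
entirely by the regime differences in mean slaughter weight and per-kg
differential cost.  Profits are margins over the differential costs only;
feed, housing and other common costs cancel in the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass


class ScenarioError(ValueError):
    """Invalid or inconsistent farm scenarios."""


@dataclass(frozen=True)
class FarmScenario:
    """One regime's annual farm parameters."""

    heads_slaughtered: int = 12_000
    mean_slaughter_weight: float = 97.1  # kg/pig
    meat_price: float = 2.2  # $US/kg
    cost_per_kg: float = 0.2045  # $US/kg, differential cost

    def __post_init__(self) -> None:
        if self.heads_slaughtered < 0:
            raise ScenarioError("heads_slaughtered must be >= 0")
        if self.heads_slaughtered > 0 and (
            self.mean_slaughter_weight <= 0 or self.meat_price <= 0 or self.cost_per_kg < 0
        ):
            raise ScenarioError("weight and price must be positive, cost >= 0")


@dataclass(frozen=True)
class FarmOutcome:
    """Annual quantity (kg) and money ($US) for one scenario."""

    heads: int
    meat_price: float
    quantity: float
    revenue: float
    cost: float
    profit: float


@dataclass(frozen=True)
class FarmComparison:
    """Welfare-friendly minus conventional differences, annual."""

    quantity: float
    revenue: float
    cost: float
    profit: float


def farm_outcome(scenario: FarmScenario) -> FarmOutcome:
    """Annual quantity, revenue, cost and profit for one scenario.

    quantity = heads x mean weight; revenue = quantity x price;
    cost = quantity x cost_per_kg; profit = revenue - cost.
    """
    q = scenario.heads_slaughtered * scenario.mean_slaughter_weight
    revenue = q * scenario.meat_price
    cost = q * scenario.cost_per_kg
    return FarmOutcome(
        heads=scenario.heads_slaughtered,
        meat_price=scenario.meat_price,
        quantity=q,
        revenue=revenue,
        cost=cost,
        profit=revenue - cost,
    )


def compare_farm(conventional: FarmOutcome, welfare: FarmOutcome) -> FarmComparison:
    """Element-wise welfare minus conventional differences.

    Both outcomes must come from the same head count and meat price —
    the farm is held fixed, only the rearing regime changes.
    """
    if conventional.heads != welfare.heads:
        raise ScenarioError("head counts differ between regimes")
    if conventional.meat_price != welfare.meat_price:
        raise ScenarioError("meat price must be fixed across regimes")
    d_revenue = welfare.revenue - conventional.revenue
    d_cost = welfare.cost - conventional.cost
    return FarmComparison(
        quantity=welfare.quantity - conventional.quantity,
        revenue=d_revenue,
        cost=d_cost,
        profit=d_revenue - d_cost,  # identity holds exactly by construction
    )
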