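"""Elasticity-calibrated partial-equilibrium model of the US pork market.

Linear demand and supply curves are backed out from one observed
price-quantity point and a pair of elasticities:

    slope = epsilon * Q0 / P0        intercept = Q0 - slope * P0

so both curves pass through the observation.  A per-kg marginal-cost saving
``delta_C`` shifts the inverse supply curve down by that amount —
equivalently the quantity-form intercept rises by slope * delta_C — and the
new equilibrium is solved where the curves cross.  Welfare accounting:

* consumer surplus: the triangle under linear demand up to the choke price,
  and its change as the trapezoid -dP * (Q0 + Q1) / 2;
* producer surplus: sector profit excluding common costs, (P - c) * Q,
  with its change taken between regimes (the geometric area above the
  supply curve is available behind a flag for comparison);
* total welfare change = dCS + dPS.

Canonical internal units: quantity in million kg (= thousand tonnes),
price and cost in $US per kg, money in million $US.  The published
quantity-form equations quote price per 1,000 tonnes; dividing slopes by
1e6 reproduces those printed coefficients, which is display only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

DEMAND = "demand"
SUPPLY = "supply"

#: reconstruction of the baseline price consistent with the published
#: equilibrium table (prices 2.203 -> 2.164); the rounder "2.2" headline
#: figure can be passed explicitly
DEFAULT_P0 = 2.2026
DEFAULT_Q0 = 9_463.032  # million kg per year, US pork market
DEFAULT_EPS_D = -1.078
DEFAULT_EPS_S = 0.417

#: literature range of US pork demand and supply elasticities used in the
#: sensitivity grid (min, average, max); the averages are kept unrounded
GRID_DEMAND = (-0.5, DEFAULT_EPS_D, -2.75)
GRID_SUPPLY = (0.2, DEFAULT_EPS_S, 0.6)


class NoEquilibriumError(ValueError):
    """Curves do not cross at a positive, unique price."""


class CurveSideError(ValueError):
    """A demand curve was supplied where supply was required, or vice versa."""


@dataclass(frozen=True)
class MarketObservation:
    """Observed market point: annual quantity (million kg), price ($/kg)."""

    Q0: float = DEFAULT_Q0
    P0: float = DEFAULT_P0

    def __post_init__(self) -> None:
        if self.Q0 <= 0 or self.P0 <= 0:
            raise ValueError("Q0 and P0 must be strictly positive")


@dataclass(frozen=True)
class Elasticities:
    """Own-price demand (< 0) and supply (> 0) elasticities."""

    epsilon_d: float = DEFAULT_EPS_D
    epsilon_s: float = DEFAULT_EPS_S

    def __post_init__(self) -> None:
        if self.epsilon_d >= 0:
            raise ValueError("demand elasticity must be negative")
        if self.epsilon_s <= 0:
            raise ValueError("supply elasticity must be positive")


@dataclass(frozen=True)
class LinearCurve:
    """Q = intercept + slope * P, quantity in million kg, P in $/kg."""

    intercept: float
    slope: float
    side: str

    def __post_init__(self) -> None:
        if self.side not in (DEMAND, SUPPLY):
            raise ValueError(f"unknown side {self.side!r}")
        if self.side == DEMAND and self.slope >= 0:
            raise ValueError("demand slope must be negative")
        if self.side == SUPPLY and self.slope <= 0:
            raise ValueError("supply slope must be positive")

    def quantity_at(self, price: float) -> float:
        return self.intercept + self.slope * price

    @property
    def choke_price(self) -> float:
        """Price at which demanded quantity hits zero (demand only)."""
        if self.side != DEMAND:
            raise CurveSideError("choke price is a demand-curve notion")
        return -self.intercept / self.slope

    def printed_form(self) -> str:
        """The equation with price per 1,000 tonnes, as published tables quote it."""
        sign = "-" if self.slope < 0 else "+"
        return (
            f"Q_{'d' if self.side == DEMAND else 's'} = {self.intercept:,.3f} "
            f"{sign} {abs(self.slope) / 1e6:.3f}P"
        )


@dataclass(frozen=True)
class PolicyComparison:
    """Full market contrast between conventional and welfare-friendly rearing.

    Quantities in million kg/yr, prices and unit costs in $/kg, money in
    million $US/yr.  Deltas are welfare-friendly minus conventional.
    """

    P0: float
    Q0: float
    P1: float
    Q1: float
    delta_P: float
    delta_Q: float
    delta_CS: float
    delta_PS: float
    delta_W: float
    pass_through: float
    revenue0: float
    revenue1: float
    cost0: float
    cost1: float
    profit0: float
    profit1: float
    CS0: float
    CS1: float

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def calibrate(obs: MarketObservation, el: Elasticities) -> tuple[LinearCurve, LinearCurve]:
    """Back out linear demand and supply curves through the observed point."""
    slope_d = el.epsilon_d * obs.Q0 / obs.P0
    slope_s = el.epsilon_s * obs.Q0 / obs.P0
    demand = LinearCurve(obs.Q0 - slope_d * obs.P0, slope_d, DEMAND)
    supply = LinearCurve(obs.Q0 - slope_s * obs.P0, slope_s, SUPPLY)
    return demand, supply


def shift_supply(supply: LinearCurve, delta_C: float) -> LinearCurve:
    """Shift the inverse supply curve down by a per-kg cost saving.

    A marginal-cost drop of ``delta_C`` $/kg moves the inverse supply curve
    vertically by delta_C, i.e. the quantity-form intercept rises by
    slope * delta_C while the slope is unchanged.
    """
    if supply.side != SUPPLY:
        raise CurveSideError("can only shift a supply curve")
    return LinearCurve(supply.intercept + supply.slope * delta_C, supply.slope, SUPPLY)


def solve_equilibrium(demand: LinearCurve, supply: LinearCurve) -> tuple[float, float]:
    """Price and quantity where the two curves cross."""
    if demand.side != DEMAND or supply.side != SUPPLY:
        raise CurveSideError("need one demand and one supply curve")
    denom = supply.slope - demand.slope
    if denom <= 0:
        raise NoEquilibriumError("slopes do not cross")
    price = (demand.intercept - supply.intercept) / denom
    if price <= 0:
        raise NoEquilibriumError(f"equilibrium price {price} not positive")
    return price, demand.quantity_at(price)


def pass_through(el: Elasticities) -> float:
    """Fraction of a per-unit cost change transmitted to the price.

    For linear curves calibrated at a common point this is
    epsilon_s / (epsilon_s + |epsilon_d|), in (0, 1); it is the closed-form
    oracle for the equilibrium solver's price change.
    """
    return el.epsilon_s / (el.epsilon_s + abs(el.epsilon_d))


def consumer_surplus_change(delta_P: float, Q0: float, Q1: float) -> float:
    """Trapezoid CS change under linear demand: -dP * (Q0 + Q1) / 2."""
    if Q0 <= 0 or Q1 <= 0:
        raise ValueError("quantities must be positive")
    return -delta_P * (Q0 + Q1) / 2.0


def consumer_surplus_level(demand: LinearCurve, price: float, quantity: float) -> float:
    """CS triangle under linear demand: (choke price - P) * Q / 2."""
    choke = demand.choke_price
    if price >= choke:
        raise ValueError(f"price {price} at/above choke price {choke}")
    return (choke - price) * quantity / 2.0


def producer_surplus_change(
    P0: float, Q0: float, c0: float, P1: float, Q1: float, c1: float
) -> float:
    """Sector-profit change excluding common costs: (P1-c1)Q1 - (P0-c0)Q0."""
    import warnings

    if P0 - c0 <= 0 or P1 - c1 <= 0:
        warnings.warn("negative margin in producer surplus", stacklevel=2)
    return (P1 - c1) * Q1 - (P0 - c0) * Q0


def producer_surplus_change_geometric(
    supply0: LinearCurve, supply1: LinearCurve, P0: float, Q0: float, P1: float, Q1: float
) -> float:
    """Alternative dPS as the change in area above the supply curve.

    Area between price line and inverse supply from the supply intercept
    price to the equilibrium: Q^2 / (2 * slope) for quantity-form
    Q = a + bP.  Provided for comparison with the profit-difference
    definition; the two differ because common costs are not netted out of
    the supply curve.
    """
    ps0 = Q0 * Q0 / (2.0 * supply0.slope)
    ps1 = Q1 * Q1 / (2.0 * supply1.slope)
    return ps1 - ps0


def policy_comparison(
    obs: MarketObservation | None = None,
    el: Elasticities | None = None,
    c0: float = 0.2045,
    delta_C: float = 0.1375,
) -> PolicyComparison:
    """Run the full pipeline: calibrate, shift supply, solve, account welfare.

    ``c0`` is the conventional differential unit cost ($/kg) and
    ``delta_C`` the per-kg saving of welfare-friendly rearing, so the
    welfare-friendly unit cost is c0 - delta_C.
    """
    obs = obs or MarketObservation()
    el = el or Elasticities()
    if delta_C < 0:
        raise ValueError("delta_C must be >= 0")
    c1 = c0 - delta_C
    demand, supply = calibrate(obs, el)
    shifted = shift_supply(supply, delta_C)
    P0, Q0 = solve_equilibrium(demand, supply)  # == (obs.P0, obs.Q0)
    P1, Q1 = solve_equilibrium(demand, shifted)
    delta_P = P1 - P0
    delta_Q = Q1 - Q0
    d_cs = consumer_surplus_change(delta_P, Q0, Q1)
    d_ps = producer_surplus_change(P0, Q0, c0, P1, Q1, c1)
    cs0 = consumer_surplus_level(demand, P0, Q0)
    cs1 = consumer_surplus_level(demand, P1, Q1)
    return PolicyComparison(
        P0=P0,
        Q0=Q0,
        P1=P1,
        Q1=Q1,
        delta_P=delta_P,
        delta_Q=delta_Q,
        delta_CS=d_cs,
        delta_PS=d_ps,
        delta_W=d_cs + d_ps,
        pass_through=pass_through(el),
        revenue0=P0 * Q0,
        revenue1=P1 * Q1,
        cost0=c0 * Q0,
        cost1=c1 * Q1,
        profit0=(P0 - c0) * Q0,
        profit1=(P1 - c1) * Q1,
        CS0=cs0,
        CS1=cs1,
    )


@dataclass(frozen=True)
class GridResult:
    """Sensitivity grid of policy comparisons over elasticity pairs."""

    cells: Mapping[tuple[float, float], PolicyComparison]

    def extreme(self, attr: str, fn=min) -> float:
        return fn(getattr(c, attr) for c in self.cells.values())

    def summary(self) -> dict[str, float]:
        return {
            "delta_PS_min": self.extreme("delta_PS", min),
            "delta_PS_max": self.extreme("delta_PS", max),
            "delta_CS_min": self.extreme("delta_CS", min),
            "delta_CS_max": self.extreme("delta_CS", max),
            "delta_W_min": self.extreme("delta_W", min),
            "delta_W_max": self.extreme("delta_W", max),
        }


def sensitivity_grid(
    obs: MarketObservation | None = None,
    demand_elasticities: Sequence[float] = GRID_DEMAND,
    supply_elasticities: Sequence[float] = GRID_SUPPLY,
    c0: float = 0.2045,
    delta_C: float = 0.1375,
) -> GridResult:
    """Policy comparison for every (epsilon_d, epsilon_s) pair on a grid."""
    if not demand_elasticities or not supply_elasticities:
        raise ValueError("elasticity lists must be non-empty")
    obs = obs or MarketObservation()
    cells = {}
    for ed in demand_elasticities:
        for es in supply_elasticities:
            cells[(ed, es)] = policy_comparison(obs, Elasticities(ed, es), c0, delta_C)
    return GridResult(cells=cells)
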