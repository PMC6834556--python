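"""Configuration, orchestration and table rendering for the full pipeline.

``run_pipeline`` chains simulate -> summarize -> costs -> farm -> market ->
grid -> bootstrap and writes every stage's output under one directory.
Rendered tables round the way the published layout does (prices to 3
decimals, million-$ amounts to 0-1 decimals, billion-$ to 4), but the
persisted CSV values are full precision.

This module also defines the bootstrap outcome functions: closed-form,
array-broadcasting re-expressions of the farm and market arithmetic in the
two mean slaughter weights.  Sampling a conventional mean weight ``m_c``
rescales the conventional market quantity proportionally
(Q0 * m_c / m_ref) and the per-kg costs inversely (c * m_ref / m_c), since
per-head costs are held fixed; prices, elasticities and mortality are not
resampled.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import bootstrap_inference as bi
from . import cost_model as cm
from . import farm_economics as fe
from . import market_equilibrium as me
from . import production_summary as ps
from . import synthetic_herd as sh
from .synthetic_herd import CONVENTIONAL, WELFARE_FRIENDLY

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MarketConfig:
    observation: me.MarketObservation = field(default_factory=me.MarketObservation)
    elasticities: me.Elasticities = field(default_factory=me.Elasticities)
    grid_demand: tuple[float, ...] = me.GRID_DEMAND
    grid_supply: tuple[float, ...] = me.GRID_SUPPLY


@dataclass(frozen=True)
class FarmConfig:
    heads_slaughtered: int = 12_000
    meat_price: float = 2.2
    mean_weights: Mapping[str, float] = field(
        default_factory=lambda: {CONVENTIONAL: 97.1, WELFARE_FRIENDLY: 103.4}
    )


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs; defaults reproduce the headline analysis."""

    herd: sh.HerdConfig = field(default_factory=sh.HerdConfig)
    costs: cm.CostConfig = field(default_factory=cm.CostConfig)
    farm: FarmConfig = field(default_factory=FarmConfig)
    market: MarketConfig = field(default_factory=MarketConfig)
    bootstrap: bi.BootstrapSpec = field(default_factory=lambda: bi.BootstrapSpec(n_reps=100_000))
    seed: int = 0

    def with_seed(self, seed: int) -> "RunConfig":
        return dataclasses.replace(
            self,
            seed=seed,
            herd=dataclasses.replace(self.herd, seed=seed),
            bootstrap=dataclasses.replace(self.bootstrap, seed=seed),
        )


def _regime_pair(mapping: Mapping[str, float]) -> tuple[float, float]:
    return mapping[CONVENTIONAL], mapping[WELFARE_FRIENDLY]


def load_config(path: str | Path | None = None) -> RunConfig:
    """Build a RunConfig from a YAML file; an absent path gives defaults.

    The YAML mirrors the dataclass structure: top-level keys ``herd``,
    ``costs``, ``farm``, ``market`` (with ``observation``, ``elasticities``,
    ``grid_demand``, ``grid_supply``), ``bootstrap``, ``seed``; each maps
    field names to values.
    """
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}

    def build(cls, data, **overrides):
        data = dict(data or {})
        data.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
        for key in ("groups", "litter_size_range", "sample_sizes", "means", "sds",
                    "grid_demand", "grid_supply"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        if "group_regimes" in data:
            data["group_regimes"] = {int(k): v for k, v in data["group_regimes"].items()}
        return cls(**data)

    market_raw = dict(raw.get("market") or {})
    market = MarketConfig(
        observation=build(me.MarketObservation, market_raw.get("observation")),
        elasticities=build(me.Elasticities, market_raw.get("elasticities")),
        grid_demand=tuple(market_raw.get("grid_demand", me.GRID_DEMAND)),
        grid_supply=tuple(market_raw.get("grid_supply", me.GRID_SUPPLY)),
    )
    cfg = RunConfig(
        herd=build(sh.HerdConfig, raw.get("herd")),
        costs=build(cm.CostConfig, raw.get("costs")),
        farm=build(FarmConfig, raw.get("farm")),
        market=market,
        bootstrap=build(bi.BootstrapSpec, raw.get("bootstrap")),
        seed=int(raw.get("seed", 0)),
    )
    return cfg.with_seed(cfg.seed)


# ---------------------------------------------------------------------------
# bootstrap outcome functions

def farm_outcome_fn(config: RunConfig) -> bi.OutcomeFn:
    """Farm differences (welfare - conventional) as functions of the two means.

    Per-head costs are fixed at their reference values (c_ref * w_ref), so
    the per-kg cost scales inversely with the simulated mean weight.
    """
    heads = config.farm.heads_slaughtered
    price = config.farm.meat_price
    w_ref_c, w_ref_w = _regime_pair(config.farm.mean_weights)
    c_ref_c = cm.per_kg_cost(CONVENTIONAL, config.costs, w_ref_c)
    c_ref_w = cm.per_kg_cost(WELFARE_FRIENDLY, config.costs, w_ref_w)
    cost_head_c = c_ref_c * w_ref_c
    cost_head_w = c_ref_w * w_ref_w

    def fn(m_c: np.ndarray, m_w: np.ndarray) -> dict[str, np.ndarray]:
        q_c, q_w = heads * m_c, heads * m_w
        rev_c, rev_w = price * q_c, price * q_w
        cost_c = heads * cost_head_c + 0.0 * m_c
        cost_w = heads * cost_head_w + 0.0 * m_w
        return {
            "farm_quantity_diff_kg": q_w - q_c,
            "farm_revenue_diff_usd": rev_w - rev_c,
            "farm_cost_diff_usd": cost_w - cost_c,
            "farm_profit_diff_usd": (rev_w - cost_w) - (rev_c - cost_c),
            "mean_weight_diff_kg": m_w - m_c,
        }

    return fn


def market_outcome_fn(config: RunConfig) -> bi.OutcomeFn:
    """Market deltas as closed-form functions of the two mean weights.

    Uses the linear-calibration pass-through algebra rather than the
    equilibrium solver so it broadcasts over replicate arrays; equality of
    the two routes at the point estimate is a tested invariant.
    """
    obs = config.market.observation
    el = config.market.elasticities
    w_ref_c, w_ref_w = _regime_pair(config.farm.mean_weights)
    c_ref_c = cm.per_kg_cost(CONVENTIONAL, config.costs, w_ref_c)
    c_ref_w = cm.per_kg_cost(WELFARE_FRIENDLY, config.costs, w_ref_w)
    rho = me.pass_through(el)

    def fn(m_c: np.ndarray, m_w: np.ndarray) -> dict[str, np.ndarray]:
        Q0 = obs.Q0 * m_c / w_ref_c
        c0 = c_ref_c * w_ref_c / m_c
        c1 = c_ref_w * w_ref_w / m_w
        dC = c0 - c1
        dP = -rho * dC
        P1 = obs.P0 + dP
        Q1 = Q0 * (1.0 + el.epsilon_d * dP / obs.P0)
        d_cs = -dP * (Q0 + Q1) / 2.0
        d_ps = (P1 - c1) * Q1 - (obs.P0 - c0) * Q0
        return {
            "market_price_diff": dP,
            "market_quantity_conventional": Q0,
            "market_quantity_welfare": Q1,
            "market_quantity_diff": Q1 - Q0,
            "market_revenue_diff": P1 * Q1 - obs.P0 * Q0,
            "market_cost_diff": c1 * Q1 - c0 * Q0,
            "market_profit_diff": d_ps,
            "market_cs_diff": d_cs,
            "market_welfare_diff": d_cs + d_ps,
        }

    return fn


def combined_outcome_fn(config: RunConfig) -> bi.OutcomeFn:
    farm_fn = farm_outcome_fn(config)
    market_fn = market_outcome_fn(config)

    def fn(m_c, m_w):
        out = dict(farm_fn(m_c, m_w))
        out.update(market_fn(m_c, m_w))
        return out

    return fn


# ---------------------------------------------------------------------------
# table rendering

FARM_ROWS = [
    ("Number of slaughter pigs", "heads", "{:,.0f}"),
    ("Expected slaughter weight (kg/pig)", "weight", "{:,.1f}"),
    ("Meat price ($US per kg)", "price", "{:,.1f}"),
    ("Production cost ($US per kg)", "cost_per_kg", "{:,.4f}"),
    ("Total sold meat quantity (Thousand kg)", "quantity_thousand_kg", "{:,.0f}"),
    ("Total revenue ($US)", "revenue", "{:,.0f}"),
    ("Total cost ($US)", "cost", "{:,.0f}"),
    ("Total Profit ($US)", "profit", "{:,.0f}"),
]


def farm_table(config: RunConfig) -> "pandas.DataFrame":
    """Two-regime + difference farm table in the published row layout."""
    import pandas as pd

    w = config.farm.mean_weights
    rows = {}
    outcomes = {}
    for regime in sh.REGIMES:
        c = cm.per_kg_cost(regime, config.costs, w[regime])
        scen = fe.FarmScenario(
            heads_slaughtered=config.farm.heads_slaughtered,
            mean_slaughter_weight=w[regime],
            meat_price=config.farm.meat_price,
            cost_per_kg=c,
        )
        out = fe.farm_outcome(scen)
        outcomes[regime] = out
        rows[regime] = {
            "heads": out.heads,
            "weight": w[regime],
            "price": out.meat_price,
            "cost_per_kg": c,
            "quantity_thousand_kg": out.quantity / 1e3,
            "revenue": out.revenue,
            "cost": out.cost,
            "profit": out.profit,
        }
    diff = fe.compare_farm(outcomes[CONVENTIONAL], outcomes[WELFARE_FRIENDLY])
    rows["difference"] = {
        "heads": 0,
        "weight": w[WELFARE_FRIENDLY] - w[CONVENTIONAL],
        "price": 0.0,
        "cost_per_kg": rows[WELFARE_FRIENDLY]["cost_per_kg"] - rows[CONVENTIONAL]["cost_per_kg"],
        "quantity_thousand_kg": diff.quantity / 1e3,
        "revenue": diff.revenue,
        "cost": diff.cost,
        "profit": diff.profit,
    }
    df = pd.DataFrame(rows)
    df.index.name = "metric"
    return df


def market_table(comparison: me.PolicyComparison) -> "pandas.DataFrame":
    """Two-regime + difference market table in the published row layout."""
    import pandas as pd

    c = comparison
    data = {
        "conventional": [c.P0, c.Q0, c.revenue0, c.cost0, c.profit0, c.CS0],
        "welfare_friendly": [c.P1, c.Q1, c.revenue1, c.cost1, c.profit1, c.CS1],
    }
    df = pd.DataFrame(
        data,
        index=[
            "Meat price ($US per kg)",
            "Total sold meat quantity (Million Kg)",
            "Total revenue (Million $US)",
            "Total costs (Million $US)",
            "Total profit (Million $US)",
            "Consumer surplus (Million $US)",
        ],
    )
    df["difference"] = df["welfare_friendly"] - df["conventional"]
    df.index.name = "metric"
    return df


def grid_tables(grid: me.GridResult, demand_values, supply_values) -> dict[str, "pandas.DataFrame"]:
    """ΔPS/ΔCS/ΔW grids (billion $US), rows = demand elasticity, cols = supply."""
    import pandas as pd

    tables = {}
    for name, attr in [("producer_surplus_change", "delta_PS"),
                       ("consumer_surplus_change", "delta_CS"),
                       ("total_welfare_change", "delta_W")]:
        df = pd.DataFrame(
            [[getattr(grid.cells[(ed, es)], attr) / 1e3 for es in supply_values]
             for ed in demand_values],
            index=[f"eps_d={ed}" for ed in demand_values],
            columns=[f"eps_s={es}" for es in supply_values],
        )
        df.index.name = f"{name}_billion_usd"
        tables[name] = df
    return tables


def render_market_text(comparison: me.PolicyComparison) -> str:
    df = market_table(comparison)
    fmt = df.astype(object)
    fmt.iloc[0] = df.iloc[0].map("{:.3f}".format)
    for i in range(1, len(df)):
        fmt.iloc[i] = df.iloc[i].map("{:,.1f}".format)
    return fmt.to_string()


# ---------------------------------------------------------------------------
# pipeline

def run_pipeline(config: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Run every stage and write its artifacts under ``outdir``.

    Returns a mapping of stage name to the file written.  Deterministic
    given the config's seeds.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    logger.info("stage simulate: generating herd")
    records = sh.generate_herd(config.herd)
    written["herd"] = outdir / "herd.csv"
    sh.write_herd_csv(records, written["herd"])

    logger.info("stage summarize: regime summaries")
    written["summary"] = outdir / "regime_summary.csv"
    ps.write_summary_csv(records, written["summary"])

    logger.info("stage costs: itemization")
    written["costs"] = outdir / "cost_itemization.csv"
    cm.write_itemization_csv(config.costs, config.farm.mean_weights, written["costs"])

    logger.info("stage farm: fixed-price comparison")
    written["farm"] = outdir / "farm_table.csv"
    farm_table(config).to_csv(written["farm"])

    logger.info("stage market: policy comparison")
    delta_C = cm.cost_shift(config.costs, config.farm.mean_weights)
    c0 = cm.per_kg_cost(CONVENTIONAL, config.costs, config.farm.mean_weights[CONVENTIONAL])
    comparison = me.policy_comparison(
        config.market.observation, config.market.elasticities, c0=c0, delta_C=delta_C
    )
    written["market"] = outdir / "market_table.csv"
    market_table(comparison).to_csv(written["market"])
    written["market_json"] = outdir / "market.json"
    written["market_json"].write_text(comparison.to_json(indent=2) + "\n")

    logger.info("stage grid: elasticity sensitivity")
    grid = me.sensitivity_grid(
        config.market.observation, config.market.grid_demand, config.market.grid_supply,
        c0=c0, delta_C=delta_C,
    )
    for name, df in grid_tables(grid, config.market.grid_demand, config.market.grid_supply).items():
        p = outdir / f"grid_{name}.csv"
        df.to_csv(p)
        written[f"grid_{name}"] = p
    written["grid_summary"] = outdir / "grid_summary.json"
    written["grid_summary"].write_text(json.dumps(grid.summary(), indent=2) + "\n")

    logger.info("stage bootstrap: %d reps", config.bootstrap.n_reps)
    results = bi.bootstrap_outcomes(config.bootstrap, combined_outcome_fn(config))
    written["bootstrap"] = outdir / "bootstrap_ci.csv"
    with open(written["bootstrap"], "w") as fh:
        fh.write("outcome,point,ci_low,ci_high,n_reps\n")
        for r in results:
            fh.write(
                f"{r.outcome_name},{r.point_estimate!r},{r.ci_low!r},"
                f"{r.ci_high!r},{r.n_reps_used}\n"
            )
    return written
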