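"""Summary statistics feeding the economic model.

Per-regime slaughter-weight moments with normal-theory 95% intervals,
mortality rates, weak-or-dead odds ratios, and the back-derivation of a
sample SD from a printed mean and 95% CI.  The 1.96 normal multiplier (not
Student's t) is used throughout because the study's printed intervals are
consistent with 1.96 standard errors.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .synthetic_herd import PigRecord, REGIMES

Z95 = 1.959963984540054  # two-sided 95% normal quantile


class InsufficientDataError(ValueError):
    """Too few usable records to compute the requested statistic."""


@dataclass(frozen=True)
class WeightSummary:
    """Sample moments of slaughter weight with a 95% normal CI (kg)."""

    n: int
    mean: float
    sd: float
    se: float
    ci95_low: float
    ci95_high: float


@dataclass(frozen=True)
class RegimeProduction:
    """One regime's production summary: weights, mortality, head count."""

    regime: str
    weight: WeightSummary
    mortality_rate: float
    heads_slaughtered: int


@dataclass(frozen=True)
class OddsRatioResult:
    """Odds ratio with a log-scale Wald 95% CI."""

    odds_ratio: float
    ci95_low: float
    ci95_high: float
    corrected: bool  # True if the Haldane-Anscombe 0.5 was applied


def summarize_weights(records: Sequence[PigRecord], regime: str) -> WeightSummary:
    """Sample mean/SD/SE and 95% CI of non-missing slaughter weights.

    Only survivors carry a slaughter weight; dead pigs are excluded by
    construction.  Requires at least two usable weights (sample SD needs
    n - 1 degrees of freedom).
    """
    weights = np.array(
        [r.slaughter_weight for r in records
         if r.regime == regime and r.slaughter_weight is not None],
        dtype=float,
    )
    n = weights.size
    if n < 2:
        raise InsufficientDataError(
            f"need >= 2 slaughter weights for regime {regime!r}, got {n}"
        )
    weights.sort()  # fixed reduction order: summary invariant under permutation
    mean = float(weights.mean())
    sd = float(weights.std(ddof=1))
    se = sd / math.sqrt(n)
    return WeightSummary(
        n=int(n),
        mean=mean,
        sd=sd,
        se=se,
        ci95_low=mean - Z95 * se,
        ci95_high=mean + Z95 * se,
    )


def sd_from_ci(mean: float, ci_low: float, ci_high: float, n: int) -> float:
    """Invert a printed normal 95% CI into the sample SD.

    With CI = mean +/- 1.96 * sd / sqrt(n), the SD is
    ((ci_high - ci_low) / 2 / 1.96) * sqrt(n).  The mean is accepted for
    interface symmetry but does not enter the formula.
    """
    if not ci_low < ci_high:
        raise ValueError("require ci_low < ci_high")
    if n < 2:
        raise ValueError("require n >= 2")
    half_width = (ci_high - ci_low) / 2.0
    return half_width / Z95 * math.sqrt(n)


def mortality_rate(records: Sequence[PigRecord], regime: str) -> float:
    """Fraction of pigs in ``regime`` that died before slaughter."""
    in_regime = [r for r in records if r.regime == regime]
    if not in_regime:
        raise InsufficientDataError(f"no records for regime {regime!r}")
    return sum(r.dead for r in in_regime) / len(in_regime)


def odds_ratio(
    events_a: int,
    nonevents_a: int,
    events_b: int,
    nonevents_b: int,
) -> OddsRatioResult:
    """Odds ratio of arm A vs arm B with a log-scale Wald 95% CI.

    OR = (events_a / nonevents_a) / (events_b / nonevents_b).  If any cell
    is zero, the Haldane-Anscombe correction adds 0.5 to all four cells; if
    both cells of an arm are zero the odds are undefined and a ValueError
    is raised.
    """
    cells = [events_a, nonevents_a, events_b, nonevents_b]
    if any(c < 0 for c in cells):
        raise ValueError("counts must be >= 0")
    if events_a + nonevents_a == 0 or events_b + nonevents_b == 0:
        raise ValueError("an arm with zero total has undefined odds")
    corrected = any(c == 0 for c in cells)
    if corrected:
        a, b, c, d = (x + 0.5 for x in cells)
    else:
        a, b, c, d = (float(x) for x in cells)
    or_ = (a / b) / (c / d)
    se_log = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_)
    return OddsRatioResult(
        odds_ratio=or_,
        ci95_low=math.exp(log_or - Z95 * se_log),
        ci95_high=math.exp(log_or + Z95 * se_log),
        corrected=corrected,
    )


def weak_or_dead_odds_ratio(
    records: Sequence[PigRecord], regime_a: str, regime_b: str
) -> OddsRatioResult:
    """Weak-or-dead odds ratio between two regimes of a record collection."""
    def counts(regime: str) -> tuple[int, int]:
        rs = [r for r in records if r.regime == regime]
        ev = sum(r.weak_or_dead for r in rs)
        return ev, len(rs) - ev

    ea, na = counts(regime_a)
    eb, nb = counts(regime_b)
    return odds_ratio(ea, na, eb, nb)


def regime_production(records: Sequence[PigRecord], regime: str) -> RegimeProduction:
    """Bundle weight summary, mortality and survivor head count for a regime."""
    weight = summarize_weights(records, regime)
    return RegimeProduction(
        regime=regime,
        weight=weight,
        mortality_rate=mortality_rate(records, regime),
        heads_slaughtered=weight.n,
    )


def write_summary_csv(records: Sequence[PigRecord], path: str | Path) -> None:
    """Emit the per-regime summary table (one row per regime)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["regime", "n", "mean", "sd", "se", "ci_low", "ci_high", "mortality"])
        for regime in REGIMES:
            prod = regime_production(records, regime)
            w = prod.weight
            writer.writerow(
                [regime, w.n, repr(w.mean), repr(w.sd), repr(w.se),
                 repr(w.ci95_low), repr(w.ci95_high), repr(prod.mortality_rate)]
            )
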