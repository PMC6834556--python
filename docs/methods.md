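# Methods

## Scope and structure

swinecon compares two pig-rearing regimes — *conventional* (surgical
castration, tail docking, teeth clipping, no enrichment) and
*welfare-friendly* (anti-GnRH immunocastration, intact tails and teeth,
environmental enrichment) — through five linked stages: a synthetic cohort
generator, production summaries, a cost model, a fixed-price farm
comparison, and an elasticity-calibrated partial-equilibrium model of the
US pork market with bootstrap uncertainty. Behavioural, endocrine and
injury-regression analyses of the underlying welfare question are outside
the package's scope; the production deltas (weights, mortality, condition
flags) enter only as parameters.

## Synthetic herd

`HerdConfig` defaults describe the study conditions: 4 treatment groups ×
8 litters, litter sizes uniform on 9–13, 50% males. Groups 1–2 (surgically
castrated) map to the conventional regime, groups 3–4 (immunocastrated) to
welfare-friendly; the mapping is configurable because the economic
contrast could equally be drawn between the extreme groups only.

Per-regime parameters, with units and rationale:

| parameter | conventional | welfare-friendly | basis |
|---|---|---|---|
| slaughter-weight mean (kg) | 97.1 | 103.4 | reported group means |
| slaughter-weight SD (kg) | 9.526 | 14.040 | back-derived from 95% CIs with n = 75, 77 |
| weaning-weight mean (kg) | 6.3 | 7.2 | typical weaning weights; the reported ~4 kg adjusted gain shrunk to the raw scale — these feed no economic quantity |
| mortality (probability) | 0.14 | 0.05 | reported rates |
| weak-or-dead odds | 0.25 | 0.25/1.89 | only the odds *ratio* (~1.89) is reported; the conventional level 0.25 (probability 0.20) was chosen once as realistic for a non-enriched nursery cohort and must exceed the mortality floor, since dead ⇒ weak-or-dead |

Weak-or-dead simulation: the flag's total probability is
`p = odds/(1+odds)`; dead pigs are always flagged and survivors are
flagged with `(p − p_dead)/(1 − p_dead)`. Configurations where `p <
p_dead` are rejected.

Weights are drawn independently per pig. A litter-level normal effect is
available (`litter_effect_sd_fraction`, default 0 — the source analysis
models a dam random effect but reports no variance component); when
enabled, the litter SD takes the given fraction of the total SD and the
individual SD is reduced so the marginal variance is preserved. Dead pigs
get no slaughter weight rather than zero, forcing downstream stages to
handle missingness. One root seed drives per-group child streams
(`SeedSequence.spawn`), so adding a group never perturbs earlier groups'
draws.

What the generator does *not* emulate: litter-correlated mortality,
seasonal effects, sex-specific growth, censoring other than death, or any
behavioural dynamics. Tests passing on synthetic herds therefore validate
the pipeline's statistics and plumbing, not biological realism.

## Production summaries

Weight summaries use the sample mean and SD (ddof = 1) over non-missing
slaughter weights, with CI = mean ± 1.96·sd/√n. The normal 1.96 multiplier
(not Student's t) matches the convention of the printed intervals;
`sd_from_ci` inverts it exactly, so round-tripping a summary recovers the
sample SD to machine precision. Back-derivation assigns n = 75 to
conventional and n = 77 to welfare-friendly (the source states only the
two sizes, not the mapping; survivor counts 88×0.86 ≈ 76 and 81×0.95 ≈ 77
support this orientation, and both are overridable).

Odds ratios use the log-scale Wald CI with the Haldane–Anscombe 0.5
correction when any cell is zero; an arm with zero total raises.

## Cost model

Two modes. *Headline* (default) takes the published per-kg differential
costs as given: 0.2045 $/kg conventional, 0.0670 $/kg welfare-friendly,
hence the 0.1375 $/kg supply shift, reproduced exactly. *Itemized*
rebuilds per-head costs from components —

- labor: wage × hours/head, 2 h/32 heads vs 1 h/180 heads at a wage of
  $28.98/h (back-solved so the saving is $1.65/head, then forward-checked);
- materials (conventional): $0.5617/head of pain-relief drugs and surgical
  equipment, in which the euro-priced analgesics (0.005 € lidocaine,
  0.14 € meloxicam/head) are already subsumed;
- vaccine (welfare): $1.6648 per male (two-dose protocol included),
  averaged over the male fraction; enrichment hardware defaults to $0 with
  a config hook;
- extra raising: mortality × $120/head average rearing cost (the stated
  `m × c` form, not `m/(1−m) × c`).

The itemized sum (≈$19.17/head conventional, ≈$6.99 welfare) lands ~3%
below the per-head figures the headline per-kg numbers imply
(≈$19.86/head); the full published breakdown is not recoverable from the
main component list. Headline mode is therefore the default and itemized
mode serves sensitivity analysis. Feed, housing and other common costs are
excluded throughout: all profits are margins over differential costs.

## Farm comparison

Quantity = heads × mean weight; revenue, cost and profit follow by the
exact identities. The meat price ($2.2/kg) is fixed across regimes — the
farm is small relative to the market. The profit difference is computed as
revenue difference minus cost difference so the accounting identity holds
bitwise. Published table values reproduce within 1%; the residual comes
from the source's own rounding (its printed revenue implies a mean weight
of 97.22 kg rather than 97.1).

## Market equilibrium

Canonical units: quantity in million kg (≡ thousand tonnes), prices/costs
in $/kg, money in million $US. Calibration, shift and solution are linear
algebra on two `LinearCurve`s; the solver's price change is verified
against the closed-form pass-through `ε_s/(ε_s+|ε_d|)` to 1e-9 on 1,000
randomized draws. `LinearCurve.printed_form` renders coefficients in the
per-1,000-tonne price unit the published equations use (slopes ÷ 10⁶),
display only.

Baseline defaults: Q₀ = 9,463.032 million kg/yr, P₀ = 2.2026 $/kg. P₀ is
a reconstruction — the source text says "$2.2" but its equilibrium table
prints 2.203 → 2.164, which 2.2026 reproduces; any P₀ can be configured.

ΔPS is the change in sector profit excluding common costs,
`(P₁−c₁)Q₁ − (P₀−c₀)Q₀`, matching the published accounting; the geometric
area above the supply curve is provided separately
(`producer_surplus_change_geometric`) for comparison but is not the
default, because the calibrated supply curve embeds common costs that the
profit accounting deliberately nets out. ΔCS uses the trapezoid under
linear demand (exact, and cross-checked against quadrature); CS levels use
the choke-price triangle. ΔW = ΔCS + ΔPS holds exactly as computed.

The sensitivity grid defaults to demand {−0.5, −1.078, −2.75} × supply
{0.2, 0.417, 0.6}. The middle row/column deliberately uses the unrounded
averages: the published mid-cells were computed with them (e.g. the
(−2.75, mid) consumer-surplus cell is 0.1733 billion at ε_s = 0.417 but
0.1744 at the rounded label 0.42). Grid reports are oriented rows =
demand, columns = supply.

Degenerate inputs: non-crossing or wrong-signed slopes raise
`NoEquilibriumError`; a negative producer margin warns but computes; a
price at/above the choke price is a domain error for CS levels.

## Bootstrap

The empirical (basic) bootstrap: each replicate draws fresh normal samples
of sizes (75, 77) from the configured means/SDs, averages them, and
re-evaluates the outcome function at the simulated mean pair; the
5th/95th percentiles of the deviations (simulated − point) are added to
the point estimate. This is implemented exactly as specified even though
it yields a 90% central interval; the (2.5, 97.5) pair reproduces the
95%-style intervals and is a config switch. Only the two weight means are
resampled — unit costs per head, mortality, prices and elasticities stay
fixed, which is why the conventional market-cost interval is degenerate.

Outcome functions must broadcast over replicate arrays; the farm and
market outcome functions in `reporting` are closed-form re-expressions of
the pipeline in the two means (market quantity scales ∝ m_c, per-kg costs
∝ 1/m), and their equality with the solver route at the point estimate is
a tested invariant, not an assumption. Non-finite replicates are dropped
with a logged count; more than 1% of them aborts the run.

Replicate counts: the library default is 10⁶ (the published design); the
test suite and the acceptance smoke run use 10⁵, at which the 5/95
percentile deviations of a linear outcome match the analytic normal
quantiles `±z₀.₉₅·√(sd₁²/n₁ + sd₂²/n₂)` within 1% and endpoints agree
with the 10⁶-replicate run within 0.5%. Sampling runs in blocks of ~4·10⁶
draws to bound memory.

## Known limitations

- Linear demand/supply is a local approximation around the observed point;
  extrapolation to the choke price (for CS levels) leans on that linearity
  far outside the data.
- The across-the-board adoption scenario ignores transition costs,
  multi-year dynamics, export markets and any willingness-to-pay premium
  for welfare-labelled meat.
- The itemized cost reconstruction is ~3% below the headline per-kg
  figures (see above); conclusions that need the exact published shift
  should use headline mode.
- Bootstrap intervals inherit the normality of the weight samples and
  vary only the two means; all other parameter uncertainty is outside the
  resampling design.
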