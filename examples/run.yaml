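# Example swinecon run configuration.
# Every value shown equals the package default, i.e. the headline analysis;
# edit any subset. Regime keys are "conventional" / "welfare_friendly".

seed: 0

herd:
  litters_per_group: 8           # 4 groups x 8 litters, study-sized cohort
  litter_size_range: [9, 13]
  male_fraction: 0.5
  slaughter_weight_mean: {conventional: 97.1, welfare_friendly: 103.4}   # kg
  slaughter_weight_sd:   {conventional: 9.5263, welfare_friendly: 14.0400}  # kg, back-derived from 95% CIs (n=75, 77)
  mortality_prob:        {conventional: 0.14, welfare_friendly: 0.05}
  weak_or_dead_odds:     {conventional: 0.25, welfare_friendly: 0.13228}  # odds ratio ~1.89

costs:
  mode: headline                 # "headline" uses published per-kg figures; "itemized" rebuilds from components
  headline_cost_per_kg: {conventional: 0.2045, welfare_friendly: 0.0670}  # $US/kg -> 0.1375 shift
  # itemized components:
  wage_per_hour: 28.9756         # back-solved so the labor saving is $1.65/head
  materials_conventional_per_head: 0.5617   # $US: pain relief + surgical equipment
  vaccine_per_male: 1.6648       # $US, two-dose anti-GnRH protocol
  male_fraction: 0.5
  rearing_cost_per_head: 120.0   # $US, average cost of rearing a replacement pig
  mortality_rate: {conventional: 0.14, welfare_friendly: 0.05}

farm:
  heads_slaughtered: 12000
  meat_price: 2.2                # $US/kg, fixed across regimes (price-taking farm)
  mean_weights: {conventional: 97.1, welfare_friendly: 103.4}

market:
  observation: {Q0: 9463.032, P0: 2.2026}   # million kg/yr; $/kg (P0 reconstructed from the equilibrium table)
  elasticities: {epsilon_d: -1.078, epsilon_s: 0.417}
  grid_demand: [-0.5, -1.078, -2.75]        # min / average / max, averages unrounded
  grid_supply: [0.2, 0.417, 0.6]

bootstrap:
  n_reps: 100000                 # 1,000,000 reproduces the full design
  sample_sizes: [75, 77]
  means: [97.1, 103.4]
  sds: [9.5263, 14.0400]
  lower_percentile: 5.0          # 5/95 convention; use 2.5/97.5 for 95%-style intervals
  upper_percentile: 95.0
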