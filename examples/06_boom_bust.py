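"""Boom-bust demography: reductions measured against the harmonic mean.

When census size alternates seasonally (large summers, small winters), the
drift-relevant baseline is the harmonic mean of the per-generation sizes; a
neutral population shows no reduction against that baseline.
"""

import numpy as np

from seglift import (
    DemographySchedule,
    Simulation,
    SimulationConfig,
    harmonic_mean_size,
    measure_ne,
)

print("published-scale window: 10 generations at 1e6 + 10 at 1e5")
print(f"  harmonic mean = {harmonic_mean_size([10**6]*10 + [10**5]*10):,.1f} "
      "(an order of magnitude below the summer peak)\n")

demo = DemographySchedule(mode="boom_bust", summer_size=2000, winter_size=200)
reductions, baselines = [], []
for seed in range(10):
    cfg = SimulationConfig(
        n_seasonal_loci=0, epistasis_y=1.0, generations_per_season=5,
        total_generations=10, demography=demo, record_every=0)
    sim = Simulation(cfg, [], np.random.default_rng(seed))
    est = measure_ne(sim, g=10, n_markers=300)[0]
    reductions.append(est.reduction)
    baselines.append(est.baseline)

print(f"neutral boom-bust runs (2000/200): baseline = {baselines[0]:.0f} "
      "(harmonic mean of the window)")
print(f"mean reduction vs harmonic mean over 10 runs = "
      f"{100 * np.mean(reductions):.1f}% (~0: drift alone is fully "
      "explained by the harmonic-mean size)")
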