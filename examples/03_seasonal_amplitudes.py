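"""Multilocus scenario: segregating-locus loss and amplitude statistics.

Simulates 60 seasonal loci under moderate epistasis at a small census size,
then summarises the amplitude distribution over three consecutive cycles at
two timepoints.
"""

import numpy as np

from seglift import (
    DemographySchedule,
    SimulationConfig,
    run_scenario,
    sample_locus_params,
    summarize_trajectories,
)

rng = np.random.default_rng(7)
loci = sample_locus_params(60, rng)
config = SimulationConfig(
    n_seasonal_loci=60, epistasis_y=8.0, generations_per_season=5,
    total_generations=600, demography=DemographySchedule(summer_size=2000),
    record_every=1)
traj, sim = run_scenario(config, loci, rng)

summary = summarize_trajectories(traj, timepoints=[100, 600], n_cycles=3)
print(summary.to_string(index=False))

print("\nSeasonal loci are steadily lost (no mutation replaces them); the "
      "survivors keep oscillating.")
row = summary.iloc[-1]
print(f"At generation 600, {int(row.n_segregating)} of 60 loci segregate "
      f"with mean amplitude {row.mean_amplitude:.3f} and the largest "
      f"single-locus amplitude is {row.max_amplitude:.3f} "
      f"(locus {int(row.max_locus_id)}).")
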