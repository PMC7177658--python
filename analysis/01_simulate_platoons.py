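#!/usr/bin/env python
"""Simulate the synthetic driver cohort used by the downstream analyses.

Generates 299 drivers (14.4% aggressive minority) in stop-and-go platoon
chains, writes the ground-truth table and a small per-driver summary to
results/cohort/, and the full episode archive to scratch/ (large,
regenerable). Downstream scripts resimulate from the same seed rather
than reading the archive, so this script is primarily a data inspection
aid.
"""

import sys
from pathlib import Path

import numpy as np

from acrboost.synthetic_traffic import (
    SimulationConfig,
    sample_population,
    simulate_platoon,
)
from acrboost.trajectory_io import write_episode_archive

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/cohort")
OUT.mkdir(parents=True, exist_ok=True)

cfg = SimulationConfig(n_drivers=299, aggressive_fraction=0.144, seed=SEED)
profiles = sample_population(cfg)
episodes, truth = simulate_platoon(profiles, cfg)

truth.to_csv(OUT / "ground_truth.csv", index=False)
write_episode_archive(episodes, Path("scratch") / "episode_archive")

n_aggr = int(truth.is_aggressive.sum())
gaps = np.array([ep.d.mean() for ep in episodes])
speeds = np.array([ep.v_f.mean() for ep in episodes])
print(f"simulated {len(episodes)} episodes ({cfg.duration:.0f} s at {cfg.dt} s)")
print(f"{n_aggr}/{len(truth)} drivers aggressive ({n_aggr / len(truth):.1%})")
print(f"mean gap {gaps.mean():.1f} m, mean speed {speeds.mean():.1f} m/s")
print(f"ground truth -> {OUT / 'ground_truth.csv'}; archive -> scratch/episode_archive/")
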