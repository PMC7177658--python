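#!/usr/bin/env python
"""Build the DFT feature matrices for the dataset emulations.

One matrix per channel set of the study grid (speed+acceleration, gap
only, all three channels), labels from the k-means ACR threshold.
Writes feature CSVs to results/features/.
"""

import sys
from pathlib import Path

import pandas as pd

from acrboost import labeling, spectral_features
from acrboost.surrogate_risk import RiskParameters, risk_table
from acrboost.synthetic_traffic import (
    SimulationConfig,
    sample_population,
    simulate_platoon,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/features")
OUT.mkdir(parents=True, exist_ok=True)

cfg = SimulationConfig(n_drivers=299, aggressive_fraction=0.144, seed=SEED)
episodes, truth = simulate_platoon(sample_population(cfg), cfg)
risk = risk_table(episodes, RiskParameters())
labeled, _ = labeling.label_drivers(risk, labeling.kmeans_threshold(risk["acr"]))
labels = pd.DataFrame(
    {
        "driver_id": [ld.driver_id for ld in labeled],
        "label": [int(ld.label == "aggressive") for ld in labeled],
    }
)

for name, channels in (
    ("speed_accel", ("speed", "acceleration")),
    ("gap", ("gap",)),
    ("all", ("gap", "speed", "acceleration")),
):
    fm = spectral_features.build_feature_matrix(episodes, labels, channels=channels)
    fm.to_csv(OUT / f"features_{name}.csv")
    print(
        f"{name:12s}: {fm.shape[0]} drivers x {fm.shape[1] - 1} amplitudes "
        f"({', '.join(channels)})"
    )
print(f"feature matrices -> {OUT}/")
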