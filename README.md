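# acrboost

Aggressive-driver recognition from car-following trajectories.

Roadside video surveillance yields vehicle trajectories for every car on a
road segment at once, which makes it an attractive data source for spotting
aggressive drivers — but actual crashes are far too rare to label drivers
with, and aggressive drivers are a small minority, so ordinary classifiers
learn to predict "normal" for everyone. This package implements a complete
pipeline for that problem, aimed at traffic-safety researchers working with
NGSIM-style trajectory tables:

1. **Average Crash Risk (ACR)** — a collision surrogate statistic computed
   from each leader–follower pair. Per 0.1 s time step,

   DSS(t) = (v_l² − v_f²) / (2 μ g) + d(t) − τ·v_f(t)

   is the margin (m) between the spacing available to the follower and the
   spacing needed to stop when both vehicles brake at the friction limit
   μg (μ = 0.7, g = 9.8 m/s²), with a reaction-time allowance τ·v_f
   (τ = 1.5 s while accelerating, 0.7 s while decelerating or idling).
   Crash Risk is CR(t) = |DSS(t)|/v_f(t) when DSS(t) ≤ 0 and 0 otherwise,
   and ACR is the time average of CR over the episode — a per-driver risk
   score in seconds.
2. **Anomaly-threshold labeling** — drivers whose ACR exceeds a threshold
   are labeled aggressive. Three threshold rules: exact two-cluster 1-D
   k-means, the IQR outlier rule Q3 + 1.5·IQR, and the 94th percentile.
3. **Spectral features** — each episode's gap, speed and acceleration
   series are reduced to the first 15 discrete-Fourier amplitudes
   |DFT_k|/N, giving fixed-length feature vectors from variable-length
   trajectories.
4. **Imbalanced-class boosting** — from-scratch AdaBoost.M1 plus
   SMOTEBoost, RUSBoost and CUSBoost (which re-balance the training sample
   inside every boosting round), one-shot SMOTE/RUS preprocessing
   baselines, and a cost-sensitive XGBoost baseline; nine algorithms in
   total, evaluated by AUPRC under 5×5 repeated stratified
   cross-validation.

A seeded synthetic-traffic module (Intelligent Driver Model platoons with a
known aggressive minority driving at short time gaps) makes the whole
pipeline testable end to end without external data.

## Worked example

Compute ACR and labels for a simulated cohort of 299 drivers:

```bash
python analysis/02_crash_risk_labels.py 1
```

prints

```
ACR distribution over 299 drivers:
  67.2% have ACR = 0 (never at rear-end risk)
  85.6% have ACR < 0.1 s (occasional, transient risk)
  kmeans       threshold 0.139 s -> 43 aggressive (14.4%, 6.0:1)
  iqr          threshold 0.003 s -> 68 aggressive (22.7%, 3.4:1)
  percentile94 threshold 0.369 s -> 18 aggressive (6.0%, 15.6:1)
leader-follower ACR Pearson r = +0.1259 over 274 pairs (near zero: a follower's risk is its own, not inherited)
```

Most drivers never enter the rear-end-risk regime; the k-means split finds
the gap between the bulk and the long right tail and labels 14.4% of
drivers aggressive (a 6:1 imbalance), while the 94th percentile pushes the
imbalance to ~15:1. The small leader–follower ACR correlation supports
reading ACR as a property of the driver rather than of local traffic.

The classifier benchmark (`python analysis/04_classifier_benchmark.py 1`)
then shows the two headline patterns: models trained on gap spectra
separate the classes almost perfectly (AUPRC ≈ 1.0) while speed+
acceleration spectra barely beat the 14% prevalence baseline (AUPRC ≈
0.2), and `analysis/05_imbalance_sensitivity.py` quantifies how each
algorithm's AUPRC drops when the imbalance ratio rises from 6:1 to ~15:1
(one-shot random undersampling degrades most, −0.28).

The same stages are available as a CLI (`acrboost simulate|risk|label|
reproduce`) and as library calls; real NGSIM-format CSVs are ingested with
`acrboost risk trajectories.csv --units us_customary --lane 6 --out risk.csv`.

## Layout

```
src/acrboost/        library: trajectory_io, synthetic_traffic,
                     surrogate_risk, labeling, spectral_features,
                     boosting, evaluation, pipeline, cli
analysis/            numbered narrative drivers writing results/
scripts/acceptance.py  one-shot reproduction of the headline numbers
docs/methods.md      models, parameters, design choices, limitations
tests/               pytest suite (unit, property and end-to-end checks)
```
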