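# Methods

## The risk statistic

For a leader–follower pair sampled at Δt = 0.1 s, the per-step stopping
margin is

    DSS(t) = (v_l(t)² − v_f(t)²) / (2 μ g) + d(t) − τ v_f(t)   [m]

with μ = 0.7 (tyre–road friction), g = 9.8 m/s², d the bumper-to-bumper
gap, and τ a reaction-time allowance. τ is switched by the **follower's**
instantaneous acceleration sign: 1.5 s when a_f > 0 (strictly), 0.7 s when
decelerating or idling. The follower is the subject whose risk is being
measured, which is why its own acceleration (taken from the data when
present, else a centred finite difference of v_f) decides the regime.

Crash Risk converts the margin into a time deficit:

    CR(t) = |DSS(t)| / v_f(t)  if DSS(t) ≤ 0,  else 0   [s]

At v_f = 0 with DSS ≤ 0 (reachable only with d = 0 and v_l = 0) CR is
defined as 0: a stationary follower cannot close the gap. Average Crash
Risk is the time average

    ACR = (Σ_i CR_i · Δt) / T,  T = N·Δt

i.e. exactly the arithmetic mean of the CR samples. Using N·Δt (not
(N−1)·Δt) for T avoids an off-by-one between the sample count and the
nominal duration and makes ACR invariant to duplicating an episode.
Consequences worth knowing: ACR is monotone non-increasing in the gap
series, invariant to episode length for a stationary risk level, and zero
iff the follower never enters the DSS ≤ 0 regime.

## Threshold rules

ACR is thresholded into binary aggressiveness labels; a driver is
aggressive iff ACR **strictly** exceeds the threshold.

* **k-means (k = 2), exact.** Optimal 1-D clusters are contiguous in
  sorted order, so the global minimiser of the within-cluster sum of
  squares is found by scanning the n−1 sorted split points — no iterative
  heuristic, no seed, and provably optimal where Lloyd-style k-means is
  only locally optimal. The threshold is the midpoint of the inter-cluster
  gap (any value in the open gap induces the same partition).
* **IQR outlier rule.** Threshold = Q3 + 1.5·(Q3 − Q1) with
  linear-interpolation ("type 7") quantiles — the result depends on the
  quantile convention, so it is fixed and documented. Note a degeneracy:
  when more than ~75% of drivers have ACR exactly 0 (common in the
  synthetic cohorts), Q3 = IQR = 0 and the rule labels every driver with
  any positive ACR aggressive, giving a *lower* imbalance than k-means
  rather than the higher one seen on real data.
* **Percentile.** The Xth percentile (default 94), declaring ≈(100−X)% of
  drivers aggressive by construction.

Leader–follower independence is checked by the Pearson correlation of
(leader ACR, follower ACR) over pairs whose leader is itself a labeled
follower; a near-zero value indicates risk is not inherited down the
platoon.

## Spectral features

Variable-length episodes are reduced to the first 15 DFT amplitudes
|DFT_k|/N per channel (gap, speed, acceleration), channels concatenated in
that fixed order. Dividing by N makes amplitudes comparable across
durations (the k = 0 amplitude is the absolute series mean). Amplitudes —
not complex coefficients — are used; phase is discarded. A band-limited
mode (keep k with k/(N·Δt) ≤ f_max, default 1.5 Hz, padded to fixed
width) is provided for workflows that think in hertz; the fixed-count mode
is the default. No windowing or detrending is applied.

## Boosting algorithms

The weak learner is a depth-limited CART tree (scikit-learn's
`DecisionTreeClassifier`; default depth 2, grid {1, 2, 3}). The AdaBoost.M1
loop is implemented here:

* initial sample weights proportional to class costs (inverse class
  frequency in cost-sensitive mode, so the minority carries the imbalance
  ratio as its relative cost; uniform otherwise), normalised to sum 1;
* per round: fit the tree on weighted data, compute the weighted error
  ε_t **on the original samples**, α_t = ½·ln((1−ε_t)/ε_t), multiply
  weights by exp(±α_t) and renormalise;
* ε_t = 0 keeps the round (capped α) and stops; ε_t ≥ 0.5 discards the
  round. For plain AdaBoost the weak learner is deterministic, so a
  discarded round ends boosting. For the three round-resampling boosters
  the round is stochastic, so a fresh resample is drawn instead, up to 10
  consecutive discards — a hard stop there produced degenerate 2–3-tree
  ensembles that are clearly not what the published algorithms do.

SMOTEBoost, RUSBoost and CUSBoost re-balance the weighted training sample
inside every round (to parity by default) before fitting the weak
learner, while ε_t, α_t and the weight update always use the original,
un-resampled samples. SMOTE synthesises minority rows by interpolating to
one of k = 5 nearest minority neighbours (λ ~ U(0,1)); synthetic rows
receive the mean weight of real minority rows for learner fitting — which
makes the learner's minority and majority weight masses equal at parity —
and are discarded afterwards. CUS clusters the majority class (k-means,
default 3 clusters) and draws the retained rows proportionally to cluster
sizes (largest-remainder rounding), preserving majority modes that
uniform undersampling would thin. With exactly balanced data and parity
targets all three boosters reduce to AdaBoost bit for bit (tested).

Ensembles score with the α-weighted mean of weak-learner class-1
probabilities (in [0, 1], used for PR curves); the classic α-weighted
majority vote is used for the training-error bookkeeping, to which the
exponential-loss bound Π_t 2√(ε_t(1−ε_t)) applies (checked on every fit
in the tests; the loop also reproduces scikit-learn's AdaBoost accuracy
exactly on a shared fixture).

Gradient-boosted trees enter as a pluggable established base algorithm
(xgboost, `scale_pos_weight` = imbalance ratio in cost-sensitive mode);
its internals are not re-implemented. The one-shot resampling baselines
apply SMOTE or RUS once to the training fold, then fit AdaBoost/XGBoost
without class costs.

## Evaluation

Precision, recall and F1 use the printed formulas with the 0/0 → 0
convention (warned). Hard labels come from thresholding scores at 0.5.
PR curves group tied scores and AUPRC is step-wise average precision
Σ (R_i − R_{i−1})·P_i — linear PR interpolation is known-optimistic and is
not used. Cross-validation is stratified 5-fold repeated 5 times
(scikit-learn's `StratifiedKFold` with per-repeat seeds); resampling and
any grid search are confined to the training folds, and the 25 fold
results are averaged unweighted (folds differ by at most one sample).
Grid search is exhaustive by inner stratified 3-fold CV maximising mean
AUPRC, ties broken toward fewer rounds, then shallower trees.

## Synthetic traffic

Followers integrate the Intelligent Driver Model at Δt = 0.1 s (Euler,
speed clamped ≥ 0, gap clamped ≥ 0.1 m, emergency deceleration capped at
8 m/s²):

    a = a_max [1 − (v/v0)⁴ − (s*/s)²],
    s* = s0 + vT + vΔv / (2√(a_max b))

plus Gaussian acceleration noise (sd 0.35 m/s², the stochastic-IDM
extension). The noise level was chosen so the share of drivers with ACR
exactly 0 moves toward the ~36% observed in real congested freeway
cohorts rather than the ~80% a noise-free IDM produces. Populations:
normal drivers T ~ N(1.5, 0.2) s (floor 0.8), s0 = 2.0 m; aggressive
T ~ N(0.6, 0.15) s (floor 0.3), s0 = 0.8 m; both share
a_max ~ N(1.5, 0.2), b ~ N(2.0, 0.3), v0 ~ N(16, 2) m/s (clipped).
Drivers are arranged in chains of 12; vehicle k follows k−1 and each
chain head follows a stop-and-go lead trace (6 ± 4 m/s sinusoid, 60 s
period, random phase, smoothed noise). Aggressiveness is shuffled over
positions, so leader and follower ground truth are independent. Exactly
round(n·fraction) drivers are aggressive; every random draw descends from
one seed. The default cohort is 299 drivers at fraction 0.144 (43
aggressive, a 6:1 imbalance at the k-means threshold); episodes are 60 s.

What the generator emulates: congested stop-and-go car-following, a
tailgating minority with elevated ACR, independence of leader/follower
aggressiveness, the NGSIM CSV schema (ids offset past the 0 = "no leader"
sentinel). What it does **not** emulate: video-extraction measurement
error, lane changes, variable episode lengths, and the within-population
heterogeneity of real drivers. Consequences for interpreting green tests:
the two prescribed time-gap populations are ~4.5 sd apart, so ACR ranks
ground truth essentially perfectly (ROC area ≈ 1.0) and gap-based
features nearly saturate AUPRC at the 6:1 imbalance; algorithm
differences only emerge at the 14:1 labeling, and the relative robustness
of per-round-resampling boosters observed on real, noisier data is only
partially reproduced — CUSBoost shows it, SMOTEBoost ties the
cost-sensitive AdaBoost baseline here (its corresponding end-to-end check
is expected to fail and is retained unweakened). Passing tests therefore
demonstrate pipeline correctness and the direction of the headline
effects, not real-data effect sizes.

## Problem sizes and determinism

The test suite and the reproduction script use cohorts of 299–300 drivers
with 60 s episodes, 5×5 CV, 50 boosting rounds and depth-2 trees; the
oracle-equivalence checks use 100–500 random instances each. These sizes
keep the full suite and the reproduction script within a few minutes on a
single CPU while leaving every comparison over the same 25 CV folds the
study design calls for. All randomness — population draws, lead traces,
acceleration noise, fold assignment, per-round resampling — derives from
explicit integer seeds; identical configurations reproduce byte-identical
output tables.

## Known limitations

* The IQR threshold rule degenerates on zero-inflated ACR samples (see
  above); it is reported but not used for the imbalance-sensitivity
  comparison, which pairs the k-means (≈6:1) and 94th-percentile (≈14:1)
  labelings.
* Episode extraction splits strictly at any leader change or frame gap;
  brief tracking dropouts are not bridged, so pair counts on real data
  may differ from analyses that bridge them.
* CR at v_f = 0 and the τ regime attribution (follower's acceleration)
  are conventions where the literature is silent; both are isolated in
  one module and easy to vary.
* The synthetic world's clean signal makes several classifiers
  indistinguishable at moderate imbalance; benchmark differences there
  should not be read as algorithm rankings for real data.
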