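# Methods

This note documents the models and procedures implemented in `hardivine`,
the defaults and why they were chosen, and what the synthetic benchmark
does and does not establish.

## Hourly temperature estimation

Most archival weather is daily min/max, while every cumulative descriptor
below is defined on hours. `weather_io.interpolate_hourly` uses an
idealized diurnal curve: temperature rises from the daily minimum at
sunrise (fixed 06:00 local standard time) along a sine to the daily
maximum at 14:00, continues on the same sine to sunset (18:00), then
decays logarithmically through the night toward the next day's minimum,
i.e. T(k) = T_sunset + (T_min,next − T_sunset) · ln(1+k)/ln(1+12) for k
hours past sunset (the minimum is reached at k = 12, the next sunrise). The first and last days are anchored by virtual
neighbours equal to themselves, which makes the interpolation exactly
translation-invariant over runs of identical days and keeps every value a
convex combination of neighbouring-day extremes. Fixed sunrise/sunset
hours were chosen over latitude-dependent ones because the downstream
features are 24-h window sums, insensitive to ±1 h anchor shifts; a
latitude field is carried through the data types for later refinement.
Timestamps are local standard time throughout — a DST jump would corrupt
the 24-values-per-day grid. Missing daily records are an error in strict
mode; permissive mode linearly imputes interior gaps of at most 3 days and
logs them.

## Feature set (117 columns)

| block | count | definition |
|---|---|---|
| cultivar one-hot | 45 | Boolean indicators over the roster (24 hybrid + 21 *V. vinifera* names); exactly one is 1 |
| days in season | 1 | days since 1 September (0 on 1 Sept; Jan–Aug count from the previous year's 1 Sept) |
| daily descriptors | 3 | that day's mean, max, min temperature (°C) |
| chilling | 3 | cumulative Utah (Richardson) units, North Carolina (Shaltout–Unrath) units, and 0–7.2 °C chill hours, from season start |
| growing degree hours | 4 | Σ max(0, T_h − b) for bases b = 0, 4, 7, 10 °C |
| freezing degree hours | 1 | Σ max(0, −T_h) (magnitude of sub-zero exposure) |
| EWMA / REWMA | 60 | windows n ∈ {2,4,…,20} × statistics {daily mean, max, min} × {forward, reversed} |

All accumulators reset at 1 September, the start of the dormancy season.
The chilling weight tables are the published stepwise forms (Utah: 0 below
1.4 °C, 0.5 to 2.4, 1.0 to 9.1, 0.5 to 12.4, 0 to 15.9, −0.5 to 18, −1
above; NC: 0 below −1.1 °C, peak weight 1.0 on (1.6, 7.2], down to −2.0
above 22.1 °C), embedded as constants.

**EWMA convention.** Weights follow the span convention α = 2/(n+1), with
weight (1−α)^lag over a hard trailing window of exactly n days,
renormalized to sum to one — the default of the tabular tooling ecosystem
this representation comes from. REWMA is *defined* as EWMA applied to the
reversed window, so the oldest day of the window carries the largest
weight; this encodes cold priming (earlier exposure conditioning the later
response) as a first-class predictor. When fewer than n days of history
exist (the first days of a record), the weights renormalize over what is
available; season accumulators are zero at 1 September by construction so
no pre-season data is required.

Moving averages intentionally run over the contiguous daily series without
a season reset: they are weather descriptors, not dormancy accumulators.

## Ensemble trainer

`model.train` implements a transparent version of the stack-and-weight
strategy of tabular Auto-ML systems:

1. **Bagging.** Each base learner is fit k times on k-fold splits
   (default `num_bag_folds = 10`); each fold model predicts the rows it
   never saw, giving leak-free out-of-fold (OOF) predictions. The bagged
   predictor for new data averages the k fold models.
2. **Stacking.** Level ℓ > 1 learners are fit on the original features
   concatenated with the level ℓ−1 OOF predictions (default
   `num_stack_levels = 5`; most experiments in this repository use 2).
3. **Weighting.** Per level, a weighted ensemble is built by greedy
   forward selection with replacement on the OOF predictions, initialized
   at the single best member and accepting only strict RMSE improvements;
   weights are selection frequencies. Initialization at the best member
   guarantees the dominance invariant: the ensemble's validation RMSE
   never exceeds the best member's.
4. **Selection.** Among all models within `tolerance` (default 0.01 °C)
   of the global best validation RMSE, the one at the lowest stack level
   wins, ties broken by fewer members — the least complex model that is
   effectively as good, which also predicts fastest.

The base-learner menu — LightGBM, random forest, ridge, k-NN, each behind
a seedable factory — is a compact, configurable stand-in for a larger
Auto-ML zoo; it spans tree ensembles, a linear model and a local smoother,
which is enough for the stacking/weighting machinery to be exercised
honestly. All randomness (splits, fold assignment, tree seeds) derives
from one integer seed stored in the artifact; identical seed + data gives
a bit-identical selected model.

The train/test split is uniform-random without stratification, with
|test| = round(K · fraction) (fraction default 0.10).

## Feature importance

*Permutation importance* draws a row subsample (default
`subsample_size = 1000`, capped at the table size) per shuffle set
(default `num_shuffle_sets = 100`), permutes one column at a time within
it, and reports the mean and SD of RMSE(shuffled) − RMSE(baseline) in °C.
A constant column scores exactly 0.

*Shapley values* use Monte-Carlo permutation sampling with an
interventional value function: v(S) is the mean model output over a
background sample with the coalition's columns replaced by the instance's
values. Contributions telescope along each sampled ordering, so local
accuracy (base value + Σφ = prediction) holds to floating-point precision
for any number of permutations; sampling error affects only the split
among features. The background is a seeded sample of training rows
(≤ 100 recommended). Features are ranked by descending mean |φ|.

## Damage potential

P(T) = 100 / (1 + exp(−(ln(1−P_h) − ln P_h) · g⁻¹ · (T − LT50_pred))),
with defaults P_h = 0.9 and g = 2 °C, meaning 10 %/90 % potential at 2 °C
above/below the predicted LT50 and 50 % at the LT50 itself. T is the
daily minimum temperature. The function is strictly decreasing in T and
point-symmetric about (LT50, 50 %). Season summaries report the maximum
daily potential and the minimum (deepest) predicted LT50.

## Synthetic benchmark

`synthetic.simulate_weather` generates daily min/max as a calendar
sinusoid with its minimum on 15 January (site parameter: mean winter
minimum, default −12 °C; seasonal half-amplitude 12 °C) plus AR(1)
deviations (persistence 0.7, innovation SD 3 °C — synoptic-scale
variability with a stationary SD near 4 °C), and a diurnal range of
8 °C with jitter tied to the innovation SD so the zero-noise limit is an
exactly periodic sinusoid.

`synthetic.simulate_lt50` integrates a daily latent hardiness state:
below a 10 °C daily-mean threshold the bud hardens in proportion to the
deficit (default 0.05 °C · day⁻¹ · °C⁻¹); above it, hardiness relaxes in
proportion to the excess, multiplied by a logistic function of accumulated
chill days (half release at 60 days, width 10), capturing the
ecodormancy transition: warmth deacclimates effectively only after
chilling is satisfied. The state is clamped between the cultivar's
initial LT50 (≈ −8 to −10 °C) and its maximum hardiness (hybrid-like:
−30 °C and below, fast rates; vinifera-like: −23 °C and shallower, slow
rates). Observations are latent values at weekly sampling dates
(1 Oct – mid-April) plus Gaussian noise, default SD 1.0 °C — the order of
real assay repeatability.

The generator's dynamics deliberately share no functional form with the
feature set (threshold integration, not EWMA; chill days, not Utah
units), so benchmark learnability is a genuine transfer between different
parameterizations of temperature history, not a round trip.

**What passing tests show — and don't.** The benchmark establishes that
the pipeline is internally correct (no out-of-fold leakage; ensembles
dominate members; known signals recovered at the noise floor) and that
the feature set can express threshold-dynamic hardiness trajectories. It
does not establish real-world accuracy: real LT50 data carry assay error
structure, cultivar × site interactions, microclimate and radiation
effects the generator omits.

## Problem sizes used in the checked-in experiments

The test-suite benchmark uses 4 sites × 5 cultivars × 4 seasons with
weekly sampling (≈ 2300 labelled rows), 5 bag folds, 2 stack levels and
the reduced tree counts — large enough for stable RMSE estimates on a
single CPU while keeping the full suite under a minute of training. The
trainer defaults (10 folds, 5 levels, full tree counts) are intended for
real-data scale work.

## Known limitations

- The diurnal interpolation ignores latitude/photoperiod drift and frontal
  passages within a day.
- The roster is fixed at training time; unseen cultivars require retraining
  (no genetic or phenological similarity backoff).
- Permutation importance on correlated features (the EWMA family is highly
  autocorrelated) splits credit across the family; interpret blocks, not
  single columns.
- Monte-Carlo Shapley cost scales as instances × permutations × features ×
  background size; for the 117-feature model use small instance sets and
  backgrounds.
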