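# hardivine

Prediction of grapevine bud cold hardiness (bud LT50) from air temperature,
and conversion of predictions into a daily freezing-damage potential.

## The problem

In cool-climate viticulture, the dormant buds that carry next year's crop
survive winter only while the ambient minimum temperature stays above their
current lethal temperature — conventionally the **LT50**, the temperature
(°C, negative) at which 50 % of a bud population is killed. LT50 is not
static: buds *acclimate* (harden) with autumn cold and *deacclimate* with
spring warmth, modulated by dormancy state and cultivar. Measuring it
(differential thermal analysis in programmable freezers) takes days per
sample, so growers get at best weekly values for a few cultivars and sites.
`hardivine` implements a statistical pipeline that predicts LT50 for any
site with an air-temperature record and turns those predictions into an
interpretable frost-risk signal.

## What the package computes

**Features.** Each sample (site, date, cultivar) is described by 117
features: 45 Boolean cultivar indicators (one-hot over the roster), days in
season (days since 1 September), the day's mean/max/min temperature,
cumulative chilling from season start under three models (Utah/Richardson
units, North Carolina/Shaltout–Unrath units, and 0–7.2 °C chill hours),
growing degree hours GDH(b) = Σ max(0, T_h − b) at bases 0/4/7/10 °C,
cumulative freezing degree hours, and 60 exponentially weighted moving
averages. For a trailing window of n ∈ {2, 4, …, 20} days over daily
mean/max/min temperature,

    EWMA_t  = Σ_k w_k T_{t-k},   w_k ∝ (1 − α)^k,   α = 2/(n+1)

weights the most recent day most, while **REWMA** applies the same weights
to the reversed window so the *oldest* day weighs most — a representation
of cold-priming effects. Hourly temperatures are estimated from daily
min/max with an idealized sine-day / logarithmic-night diurnal curve.

**Model.** A stacked ensemble regressor: each base learner
(gradient-boosted trees, random forest, ridge, k-NN) is bagged over k folds
with leak-free out-of-fold predictions; higher stack levels consume the
original features plus the previous level's out-of-fold predictions; every
level gets a weighted ensemble fit by greedy forward selection (Caruana
style), and the final model is the *least complex* one within a small RMSE
tolerance of the best. Performance is reported as RMSE (°C), with signed
prediction error defined as predicted − observed.

**Importance.** Permutation importance (mean RMSE increase when one feature
is shuffled across rows, over many shuffle sets) and Monte-Carlo Shapley
values with an interventional background-marginal value function, which
satisfy local accuracy exactly.

**Damage potential.** For deployment, a predicted LT50 and the daily
minimum temperature T give a damage potential (percent)

    P = 100 / (1 + exp(−(ln(1 − P_h) − ln P_h) · g⁻¹ · (T − LT50_pred)))

With the defaults P_h = 0.9 and g = 2 °C: P = 10 % at T = LT50 + 2 °C,
90 % at T = LT50 − 2 °C, and 50 % at T = LT50.

**Synthetic benchmark.** Because real LT50 archives are not bundled, a
generator produces multi-site, multi-season daily weather (calendar
sinusoid + AR(1) deviations) and cultivar-specific latent LT50 trajectories
from threshold acclimation/deacclimation dynamics with a chilling-gated
deacclimation — deliberately *not* the inverse of the feature set — so
every stage of the pipeline is testable against known ground truth.

## Worked example

```bash
hardivine simulate  --out sim --n-sites 2 --n-cultivars 3 --n-seasons 2 --seed 42
hardivine featurize --weather-dir sim --lt50 sim/lt50.csv --out feat
hardivine train     --features feat --out model --bag-folds 5 --stack-levels 2 --fast --seed 42
hardivine evaluate  --model model --out eval
```

prints

```
wrote benchmark (348 observations) to sim
wrote 348 x 117 feature matrix to feat
selected ensemble@L2 (validation RMSE 1.356 degC)
test RMSE 1.200 degC over 35 rows
```

The simulated observations carry 1.0 °C measurement noise, so a held-out
RMSE of 1.20 °C means the model has recovered essentially all of the
learnable temperature signal: it predicts a bud's lethal temperature to
about a degree. `eval/rmse.csv` breaks the RMSE down by cultivar, and
`model/model_manifest.json` records every base model's validation RMSE and
the ensemble weights. Turning predictions into frost risk:

```bash
hardivine damage --predictions preds.csv --out dmg   # date,t_min,lt50_pred columns
```

```
date,t_min,lt50_pred,damage_potential
2023-01-14,-24,-26.0,9.999999999999998
2023-01-15,-27,-26.2,70.65921139768864
2023-01-16,-21,-25.8,0.5100318170652064
```

On 15 January the minimum dipped 0.8 °C *below* the predicted LT50, giving
a 71 % damage potential — a night a grower would want flagged; the adjacent
days sit at 10 % and 0.5 %.

The same pipeline is scriptable from Python (`hardivine.synthetic.make_benchmark`,
`hardivine.features.build_feature_matrix`, `hardivine.model.train`, …);
see `docs/methods.md` for the modelling details and parameter defaults.

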