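# nicheshift

Ecological niche modelling for interacting species pairs: a library that
takes two species' occurrence records and a shared stack of environmental
rasters and produces habitat-suitability models, past/future scenario
projections, abiotic niche-overlap metrics, and a threshold-free
vulnerability assessment — the workflow used to ask how climate change may
pull apart a predator–prey (or other ectotherm–endotherm) interaction.

It is aimed at spatial ecologists who want the whole chain — occurrence
cleaning, spatial thinning, target-group background sampling, maximum-entropy
modelling, AICc-based regularization selection, GCM ensemble projection,
overlap and vulnerability statistics — as composable, deterministic Python
functions, with a synthetic-data generator that stands in for downloaded
occurrence/climate data so every stage can be tested with known ground truth.

## The model

Habitat suitability is estimated with a maximum-entropy (MaxEnt) model: a
log-linear (Gibbs) density over the landscape's background cells,

```
p_λ(x) = exp(Σ_j λ_j f_j(x)) / Z,      Z = Σ_background exp(η(x)),
```

where the features `f_j` are linear, quadratic, product and hinge expansions
of the environmental layers, scaled to [0, 1] on the training data. The
coefficients maximize the L1-penalized mean presence log-likelihood

```
max_λ  mean_presence η(x) − ln Z − Σ_j rm · β_j σ_j/√m · |λ_j|
```

with `m` the presence count, `β_j` the published per-feature-class defaults,
`σ_j` the presence standard deviation of feature `j`, and `rm` the
regularization multiplier, selected over a grid by the small-sample Akaike
criterion `AICc = 2k − 2 lnL + 2k(k+1)/(n−k−1)` (`k` = nonzero coefficients,
`n` = presences). Models are evaluated by presence-vs-background ROC AUC
(Mann–Whitney form) under k-fold cross-validation.

Predictions come on two scales: **raw** (the density itself; sums to 1 over
the prediction extent) and **cloglog** (`1 − exp(−e^(η−r))`, a bounded
relative-suitability scale with the entropy-based offset `r` fixed from
training). Niche overlap between two species uses normalized suitability
surfaces `p`, `q`:

* Schoener's `D = 1 − ½ Σ|p_i − q_i|`
* Warren's `I = 1 − ½ Σ(√p_i − √q_i)²`  (always ≥ D)

The vulnerability assessment never thresholds the maps: with `H` the sum of
suitability over a region, each species' change is `100·(H_new − H_ref)/H_ref`
and the co-occurrence area (the geometric intersection of the two buffered
ranges) is scored with the combined form
`100·((HP_new + HO_new) − (HP_ref + HO_ref))/(HP_ref + HO_ref)`.

## Worked example

`examples/04_full_pipeline.py` runs the default desk-scale study — an
ectotherm-analogue predator (temperature-limited) and an endotherm-analogue
prey (substrate- and moisture-driven) on a shared synthetic landscape, with
three warming-family futures and two paleo periods:

```
$ python examples/04_full_pipeline.py
Model evaluation (5-fold cross-validation)
  ectotherm_predator: mean AUC = 0.775 (rm = 2.0)
  endotherm_prey: mean AUC = 0.759 (rm = 2.0)
Abiotic niche overlap
  Schoener's D = 0.454
  Warren's I   = 0.743
Vulnerability assessment (% change in summed suitability)
                          LGM-like       MH-like   RCP2.6-like   RCP4.5-like   RCP8.5-like
  Overlap area             104.73%        -0.43%        -4.49%       -10.62%       -17.02%
  ectotherm_predator        17.83%        -3.65%       -26.21%       -50.34%       -69.60%
  endotherm_prey           374.67%         2.21%        12.27%        20.02%        23.51%
```

Reading the table: future (RCP-like) columns are current-to-future change,
paleo columns are past-to-current change. The temperature-limited predator
loses suitable habitat under every warming scenario while the
temperature-indifferent prey gains — the ectotherm/endotherm mismatch the
workflow is built to expose — and the co-occurrence area sits between the
two. The other examples each demonstrate one capability (model fitting and
evaluation, overlap metrics, scenario projection) with a few dozen lines.

A thin CLI wraps the same functions: `nicheshift run --seed 7 --out run/`,
plus `generate`, `clean`, `thin`, `bias`, `background`, `report`.

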