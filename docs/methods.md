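# Methods

This note documents the models and procedures implemented in `nicheshift`,
the defaults they ship with, and the design choices made where the published
workflow it follows leaves details open.

## Estimator

The suitability model is a maximum-entropy density over background cells:
`p_λ(x) ∝ exp(Σ_j λ_j f_j(x))`, fitted by maximizing the mean presence
log-likelihood under that density minus an L1 penalty. The optimization uses
the split `λ = λ⁺ − λ⁻` reformulation (both parts nonnegative), which turns
the penalized problem into a smooth, convex, box-constrained one solved with
L-BFGS-B from a zero start. Fits are therefore deterministic: no random
initialization, monotone objective decrease, convergence when the projected
gradient falls below `1e-6` (configurable) or after 10,000 iterations.

**Normalization set.** By default the presence samples are appended to the
background before normalization (`add_samples_to_background=True`). This is
the estimator's standard behaviour and is load-bearing: a hinge feature whose
support lies entirely among the presences would otherwise have an
unattainable presence expectation, and its coefficient would diverge. With
the samples included, the background density can always match any presence
feature mean, so coefficients stay bounded. Features that are constant across
the (augmented) background are pinned at zero — they cannot shape the
density. Setting the flag to `False` normalizes over exactly the supplied
background rows, which is the form in which the moment-matching solution has
a closed form (single binary feature with background split n₁/n₀ and presence
mean f̄ gives `λ = ln(f̄·n₀ / ((1−f̄)·n₁))`); the test suite verifies that
identity to 1e-4.

**Features.** Linear, quadratic, product and hinge classes; default
`linear + quadratic + hinge` with products off, following the algorithm's
standard auto-feature behaviour for large samples (the workflow this package
re-creates does not state its feature classes). All features are scaled to
[0, 1] using training-data bounds only; hinge knots are evenly spaced over
`[min, max)` (20 per variable by default; the pipeline default uses 8 to keep
desk-scale fits fast). Constant variables are dropped with a warning.

**Penalty.** `c_j = rm · β_class(m) · σ_j/√m`, with `β_class` the published
class defaults interpolated in the presence count m (linear/quadratic/product:
1.0 at m=10, 0.2 at m=30, 0.05 at m≥100; hinge: 0.5 throughout) and `σ_j` the
presence standard deviation of feature j, floored at 0.01 to keep penalties
positive for near-constant features. `rm = 0` is accepted (it was the
selected value for one species in the study this follows) but logs an
overfitting warning. Coefficients with `|λ| ≤ 1e-7` count as zero; that count
is the k in AICc.

A caution about the regularization path: the *number* of nonzero coefficients
is not guaranteed to be monotone in `rm` — with strongly correlated hinge
bases a feature can re-enter the support as the penalty grows (we observed a
λ of 0.08 appearing between rm=2.0 and rm=2.5 on one dataset). The package's
canonical synthetic dataset does show a monotone path over the 0.5–3 grid,
and the provable property (the base-weighted L1 norm of the solution is
non-increasing in rm) is asserted in the unit tests.

**Output scales.** `raw` is the density renormalized over the prediction
extent's valid cells (sums to 1). `cloglog` is `1 − exp(−e^(η−r))` with
`r = lnZ − H` fixed from training, H the entropy of the training raw
distribution; it is the bounded display scale used for suitability sums. The
workflow re-created here never names its display scale; cloglog is the
modern default and both are available everywhere (`scale=` argument). With
clamping on (default for projection), variables are truncated to their
training bounds before feature evaluation, so extrapolated cells saturate
rather than explode.

## Model selection, evaluation, diagnostics

`select_rm` fits the model on all presences for each candidate rm and scores
`AICc = 2k − 2 lnL + 2k(k+1)/(n−k−1)` with `lnL = Σ_presences ln raw(x)`
(raw over the training normalization set), `k` the nonzero-coefficient count
and `n` the presence count; candidates with `n ≤ k+1` are reported non-finite
and excluded. Evaluation is presence-vs-background AUC in exact Mann–Whitney
form (ties 0.5), under k-fold (default 5) cross-validation with seeded fold
assignment; the final projection surface is the cell-wise mean of the k
replicate predictions (a full-data refit is what `fit_maxent` on the complete
table gives, and is used for the variable-importance table).

Percent contribution attributes each optimizer iteration's training-gain
improvement to variables in proportion to their features' coefficient
movement (product features split evenly), then normalizes to 100. The
single-coordinate attribution of the reference tool is not reproducible under
a quasi-Newton step, where all coordinates move at once; this is the natural
generalization and reduces to it in the coordinate-wise limit. Jackknife
importance refits with only/without each variable and reports the
regularized training gain (`mean presence ln raw + ln n_background`).
Marginal response curves sweep one variable over its training range with the
others fixed at background means, on the cloglog scale.

## Occurrence preparation

Cleaning applies exactly three filters — drop rows with a missing coordinate,
drop infraspecific ranks (subspecies/variety/form) when requested, drop exact
(species, lon, lat) duplicates keeping the first — preserving survivor order;
it is idempotent. A datum-transform hook (a callable on the table) runs
before filtering for data mixing geodetic datums; the default is identity.

Thinning lays a temporary square grid (default 5 km, converted to degrees at
the study-area mid-latitude; a fixed-degree override exists) anchored at the
raster origin and keeps one record per occupied cell, chosen uniformly at
random under a seed — not "first record", which would make results depend on
input file order. The sampling-bias surface counts target-group records per
model-grid cell, optionally Gaussian-smoothed with total mass preserved;
cells with no target-group records get zero weight (an explicit uniform
fallback is available for sparse data). Pseudo-absences are drawn
multinomially across cells proportional to the bias weights, with
replacement at the cell level, uniformly placed within each cell; 10,000 by
default.

## Rasters

All layers share one regular lon/lat grid (WGS84) with a single validity
mask; files are single-band ESRI ASCII grids (plain text), polygons GeoJSON.
Range masking tests cell centers against the buffered polygon; buffering
happens in a local equirectangular metric frame (x scaled by cos of the
polygon's mid-latitude), accurate to well under a cell at kilometre scales —
a full geodetic pipeline is out of scope. The terrain ruggedness index is the
root-sum-of-squares of the eight neighbour elevation differences (edge cells
use the neighbours that exist; nodata propagates); a mean-absolute-difference
variant was considered and rejected to keep one documented definition.
Correlation pruning computes Pearson r over jointly valid cells, scans pairs
by descending |r|, and drops the lower-priority member of any pair at or
above the threshold (default 0.8) until all survivors are below it; the
priority list is an explicit, user-supplied total order — a reproducible
stand-in for the expert judgement that typically picks survivors. Coarser
scenario stacks are harmonized to the model grid by nodata-aware bilinear
resampling (nearest-neighbour for categorical layers).

## Projection and scenario averaging

A scenario bundles one climate stack per GCM plus static layers (elevation,
ruggedness, soil) held constant across periods. Ensemble averaging operates
on the model *outputs* — the per-GCM suitability maps are averaged cell-wise,
in name-sorted order so the mean is exactly permutation-invariant — rather
than on averaged climate inputs; averaging inputs is possible by building a
single-GCM scenario from pre-averaged layers. A cell is nodata in the mean
iff it is nodata in any input, so scenario sums are always over one common
footprint.

## Overlap and vulnerability

Schoener's D and Warren's I are computed on suitability surfaces normalized
to sum 1 over the *shared* validity mask (the intersection of both species'
cells — the metrics are undefined where either surface is missing). They are
computed on the raw scale by default (scale-free after normalization;
configurable to cloglog). Suitability sums H for the vulnerability assessment
use the bounded cloglog scale by default (configurable to raw): in a
threshold-free design a sum of bounded relative suitabilities is the natural
"amount of suitable habitat".

Direction convention: future scenarios report current-to-future change,
`100·(H_f − H_c)/H_c`; paleo periods report past-to-current change,
`100·(H_c − H_p)/H_p`, so every entry reads "change relative to the earlier
state" and negative always means loss. The combined co-occurrence statistic
is computed over the geometric intersection of the two buffered ranges and
is reported with exactly the sign the formula yields — no magnitude-only
convention is applied, even for small negative values. Percentages are
rounded to two decimals in tables; the underlying H sums are stored in the
report for exact reproduction of every entry.

## Synthetic study system

The generator emulates the statistical structure of the real inputs, not
their physics. Environmental layers are white noise convolved with a
Gaussian kernel (σ = 1.5 cells by default) and standardized — cheap,
controllable spatial autocorrelation; a latitudinal gradient layer is always
added. Correlated pairs mix `B = ρA + √(1−ρ²)·E` with E empirically
orthogonalized against A, so realized Pearson correlations equal ρ exactly.
True niches are log-linear in the standardized layers (`s ∝ exp(Σ λ_j z_j)`,
normalized to sum 1); presences are multinomial in `s × effort`, with a
smooth multiplicative sampling-effort field emulating uneven survey
coverage, and 5% injected dirty rows (duplicates, missing coordinates,
subspecies tags) so the cleaning stage always has work. Range polygons are
convex hulls of above-quantile suitability cells. Scenarios shift listed
layers cell-wise (`x·factor + shift`) and hold the rest constant.

The default study pair is designed to exhibit the mismatch the workflow
exists to measure: species A (ectotherm analogue, buffer 1.5 km) is
cool-adapted (`λ = −2` on the temperature-like layer, `+1.5` on a
moisture-like layer); species B (endotherm analogue, buffer 36 m) is
temperature-indifferent and driven by substrate and a second moisture layer
(`+1.5`, `+1.0` on percent-sand). The warming family raises temperature by
0.5/1.0/1.5 standard deviations (RCP-like 2.6/4.5/8.5) with a mild moisture
increase; three GCM variants scale each shift by 0.8/1.0/1.2. The glacial
period is cool and markedly drier; the mid-period a small perturbation. Under
these conditions A loses habitat in all futures and B gains — the directional
pattern the end-to-end tests assert.

What the generator does **not** emulate: real bioclimatic covariance
structure, GCM physics, coordinate-uncertainty errors, taxonomic ambiguity,
or detection/effort confounding beyond a smooth multiplicative field.
Passing tests therefore demonstrate the correctness of the machinery and the
qualitative behaviour of the workflow under known truth — not predictive
skill on real occurrence data.

## Problem sizes and determinism

The default study runs on a 50×50 grid (Great-Plains-like window, 0.05°
cells) with 8 climate fields plus elevation, ruggedness, sand and the
gradient (12 predictors, of which the correlated pairs lose ~4 to pruning),
500 presences per species before cleaning, 10,000 background points, the rm
grid 0.5–3 in 0.5 steps, and 5 folds — sizes chosen so a full two-species
run completes in tens of seconds while every stage still has realistic
statistical behaviour. One master seed fans out to named per-stage sub-seeds
(mixed through `SeedSequence` with a CRC of the stage tag); species-level
seeds are keyed by species *name*, so relabelling the pair swaps report rows
without changing a single draw. Repeated runs under one master seed are
byte-identical, including all written maps and tables.

## Known limitations

- Single-band text rasters and lon/lat grids only; no general CRS
  reprojection (the metric-buffer path covers the study design).
- No categorical or threshold feature classes.
- AUC against background is a relative-ranking metric; absolute values are
  deflated when background and presences overlap spatially, as with heavy
  target-group bias correction.
- The co-occurrence statistic depends on the H scale (cloglog vs raw);
  comparisons across configurations must hold that choice fixed.
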