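# Methods

This note documents the model behind `pathocarbon`, its assumptions, the
defaults that matter, and what the synthetic components do and do not
capture.

## Emission accounting

Operational emissions only: the electricity used by inference is converted
to CO₂eq at the grid's carbon intensity. Embodied emissions (hardware
manufacture, transport, buildings), data storage, and model training or
retraining are out of scope by design; for regulated clinical deployments,
models are typically frozen, so inference dominates the recurring cost.

The accounting chain is linear in tile count, per-tile energy and grid
intensity. Per scenario task, kg CO₂eq = tiles × (kWh per 10⁷ tiles)/10⁷ ×
intensity, summed over tasks. This bilinearity is load-bearing: it is what
justifies the multiplicative driver coupling in the projections and makes
every aggregate an exact sum of its parts (tested as additivity and
permutation invariance).

Per-model energies are normalised to a reference workload of 10⁷ tiles so
models of very different throughput are comparable; the default device
profile is a Quadro-6000-class workstation GPU, the pragmatic choice for
clinical desktops over data-centre accelerators.

## Tile workloads

A WSI of `n_pixels` tiles into `ceil(n_pixels / edge²)` non-overlapping
square tiles; the default edge is 512 px, a common computational-pathology
patch size (configurable). The tissue and ROI input modes scale the full
tile count by the slide's tissue or ROI area fraction and round up. Tissue
and ROI tile counts are derived from area fractions rather than spatial
masks: no images exist in this package, and the area fractions are exactly
the quantities the emission model consumes. Ceiling monotonicity gives
roi ≤ tissue ≤ wsi per slide, which propagates to every aggregate.

## Synthetic cohorts

The generator emulates a two-organ institute cohort: by default 5 prostate
and 8 breast cases with log-normal slides-per-case (medians 40 and 16,
matching a digitised census of 223 prostate slides over 5 cases and 140
breast slides over 8), log-normal pixels per slide (median 4×10⁹ px — a
gigapixel 40× scan — log-sd 1.0), Beta(2.5, 4.5) tissue fractions, and ROI
fractions drawn as Beta(2, 2) multiples of the tissue fraction, which
enforces roi ≤ tissue by construction.

File sizes follow a concave compression curve `bytes = a·pixels^b·ε`
(defaults a = 25, b = 0.8; scanner compression is relatively more
effective on large scans) with log-normal noise ε. The noise sd is solved
analytically — via the closed-form Pearson correlation of a bivariate
log-normal pair — so the raw-scale pixel–file-size correlation hits a
configured target, 0.58 by default (a moderate correlation: file size
alone does not determine computational load, which motivates the tissue
fraction as a first-class input). Targets above the noise-free ceiling for
the configured spread are rejected with a configuration error. Because
pixel counts are heavy-tailed, the *sample* correlation at a few thousand
slides still fluctuates around the target by a few hundredths.

One root seed feeds per-purpose child streams (slides, pixels, fractions,
file sizes), so adding a field never reshuffles unrelated draws and every
downstream CI is reproducible.

What the generator does not emulate: spatial tissue structure, scanner- or
stain-specific compression, correlations between tissue fraction and
specimen type, and inter-case heterogeneity beyond the slide-count
distributions. Passing tests therefore demonstrate the accounting and
statistics are correct on realistic *shapes* of data, not that any
particular institute's numbers are reproduced.

## Calibration and the parameter–energy law

The packaged 30-model table (20 classification, 10 segmentation) is
synthetic: per-model energies are drawn from a log-log law
(log₁₀ kWh = −5.36 + 0.8·log₁₀ params, scatter sd 0.25 dex) with realistic
parameter counts, because measured per-model energies are generally
institution- and setup-specific. Users auditing a real deployment should
substitute measured values; the table's schema is one CSV row per
model × device.

Size classes pick, per task type, the minimum-, median- and maximum-energy
model. For even counts the *lower* median is used so "medium" is always a
real model; ties break lexicographically on model name for determinism.

The parameter–energy regression is OLS of log₁₀ energy on log₁₀ parameter
count — the standard scaling family, and the only sensible one across five
orders of magnitude of model size. Uncertainty comes from a nonparametric
pairs bootstrap over models (default 2000 draws, seeded); resamples with a
degenerate design (all identical parameter counts) are redrawn. The point
fit uses statsmodels; the bootstrap uses a vectorised closed-form
two-parameter OLS for speed. The multitask model has no measurable
instance, so its energy is the regression's plug-in prediction at 5.4×10¹¹
parameters, with a percentile CI over the bootstrap predictions. This is a
long extrapolation beyond the calibrated range and its wide CI should be
taken seriously; the draws are propagated into every multitask-scenario
CI rather than collapsed to the point estimate.

Pruning is modelled as a piecewise-linear energy multiplier over the
pruned fraction; the default curve runs from (0, 1.0) to (0.40, 0.75) —
pathology classifiers pruned up to 40% with retained accuracy have been
observed to emit 20–30% less, and the midpoint of that band is used.
Requests beyond the last calibrated knot are refused rather than
extrapolated.

## Confidence intervals

CIs are percentile bootstraps (default 2000 resamples, seeded). The
default uncertainty source is per-run energy measurement noise,
multiplicative log-normal with σ = 0.02 on the log scale — narrow, in line
with the tight repeatability of hardware energy measurement. Case
resampling is available (`resample_cases=True`) but off by default: the
yearly case census of an institute is a fixed quantity, not a sample from
a superpopulation, and treating it as one inflates the CI with variance
that has no operational meaning. With this design the CI always brackets
the noise-free point estimate, and its width vanishes as σ → 0.

## Sequestration equivalents

Trees: CO₂eq kg / 21.8 (an average mature tree's yearly uptake), rounded
up — a fraction of a tree cannot absorb the remainder. Forest area:
tonnes divided by the world forest's mean annual sequestration rate,
7.6×10⁹ t over 40.6×10⁶ km² ≈ 187.2 t/km²/yr, kept as a real number;
regional fractions divide by the region's forest area. Both conversions
are degree-1 homogeneous (up to the integer ceiling on trees). The tree
uptake figure varies a lot by species and age; these equivalents are
communication devices, not offset accounting.

## Extrapolation

National and global pathology case counts are not registered anywhere, so
regions are scaled from an institute anchor: total cases = region cancer
cases × (institute total / institute cancer). The default anchor is 4 804
cancer cases among 40 356 total (4 804 + 35 552 non-cancer); the anchor is
a plain dataclass, so either reading of an ambiguous census can be
configured. Extrapolations default to the tissue input mode: whole-WSI
input is wasteful and ROI-only input discards diagnostic context, so
tissue is the defensible deployment assumption. A survey-based national
case count about 3.8× the cancer-anchored extrapolation indicates the
approach is conservative; the underestimation factor is exposed as a
first-class quantity.

The packaged region table is synthetic in its country rows (approximate
cancer incidences, renewable shares and forest areas); its Germany row
uses a direct 0.40 kg/kWh intensity (a direct value always overrides the
linear mix, which only approximates real grid data), and its World row's
cancer count (20 625 588) is *inferred* so that the anchor ratio
reproduces a published world pathology-case total of 173 265 243 — it is
not a sourced incidence figure.

## Projections

Four drivers on a 2023–2052 year grid: renewable share, model complexity,
hardware efficiency, case counts. Coupling is multiplicative and
separable — the only rule consistent with linear emission accounting:

E(y) = E0 · [cmplx(y)/cmplx(y0)] · [cases(y)/cases(y0)] ·
[I(ren(y))/I(ren(y0))] / [eff(y)/eff(y0)].

Anchors are interpolated monotonically (PCHIP) in log space for positive
drivers — growth processes — and linearly, clamped to [0, 1], for the
renewable share; beyond the outermost anchors the edge-segment slope is
continued. A growth-rate spec is converted to end anchors and reproduces
compound growth exactly. Bands come from perturbing anchors per bootstrap
draw (log-normal, or logit-normal for the share; default 2000 draws,
seeded) and re-interpolating whole paths; the best/worst emission paths
are the per-year 2.5/97.5 percentiles of the drawn paths, and the mean
path uses unperturbed anchor means. The renewables "mean" scenario is the
per-year average of the planned and below-2 °C anchor paths.

The packaged renewable anchors are grounded in published outlooks (world
share ≈ 20% in 2023; 55% planned and 86% below-2 °C by 2050); the
complexity, efficiency and case-count anchors are synthetic growth
assumptions (≈ 23%/yr, ≈ 15%/yr and ≈ 1.7%/yr respectively, with
uncertainty growing with horizon) — all four ship as an editable CSV and
none is hard-coded as truth.

## Numerical choices

- Trace integration: trapezoidal rule — exact for piecewise-linear draws,
  and checkable against an independent fine-grained Riemann oracle.
- Rounding: case counts to nearest integer; trees rounded up; emissions
  kept at full precision internally, 3 significant figures in reports.
- Ties: argmin/argmax over models break on model name; medians use the
  lower rank.
- Degenerate inputs fail loudly and specifically: empty cohorts,
  non-monotone traces, all-equal parameter counts, missing calibrations,
  duplicate regions, mismatched year grids, under-specified drivers.
- Bootstrap percentile bands are clipped to contain the mean path, which
  guards the best ≤ mean ≤ worst ordering against percentile jitter at
  small draw counts.
- Seeds: every stochastic routine takes an explicit seed; composite runs
  derive child seeds via `numpy.random.SeedSequence` spawning.

## Problem sizes

The test suite and the acceptance script run on the study-shaped 13-case
cohort (≈ 360 slides), the 30-model calibration table, a 10-region table
and 2000-draw bootstraps (statistical recovery checks use 200 replicates
of 30-model tables with 1000 draws each); these sizes keep every check
well-resolved statistically while the whole suite runs in seconds.

## Known limitations

- Headline tonnages depend entirely on the calibration table; with the
  synthetic table they demonstrate structure (ratios, monotonicities,
  CI behaviour), not absolute institutional footprints.
- Uniform technology adoption is assumed across regions; real
  digital-pathology penetration is very uneven.
- The grid-intensity mix is linear between a fossil and a renewable
  endpoint; real grids have structure (nuclear, imports, diurnal cycles)
  that only a direct intensity value captures.
- Driver trajectories are independent in the bootstrap; correlated shocks
  (e.g. efficiency and complexity co-evolving) are not modelled.
- Tissue/ROI fractions are metadata, not outputs of detection models; the
  energy cost of the detection models themselves appears only in the
  pathomics comparator's detection pass.
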