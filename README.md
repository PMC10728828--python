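# pathocarbon

Operational carbon-footprint modelling for deep learning in digital
pathology.

Digital pathology turns histology glass slides into gigapixel whole-slide
images (WSIs) that deep-learning models consume as fixed-size square tiles.
Running one or several models over every case of a pathology institute —
let alone a country — is a substantial computational workload, and its
electricity use carries a global-warming cost that is rarely quantified.
`pathocarbon` is a tested, reusable pipeline for putting numbers on that
cost: it is aimed at pathology institutes auditing the CO₂-equivalent
(CO₂eq) burden of planned deep-learning deployments, and at researchers
studying reduction strategies (data reduction, smaller models, pruning,
pathomics) and long-range emission trajectories.

## The model

Emission accounting is linear end to end. For a deployment scenario with
tasks *j* applied to every tile of the chosen data-input mode,

```
CO2eq [kg] = Σ_j  N_tiles · (E_j / 10⁷) · I
```

where `N_tiles` is the cohort's tile count under the mode (all tiles,
tissue-containing tiles only, or region-of-interest tiles only), `E_j` is
the model's calibrated energy in kWh per 10⁷ tiles on the chosen device,
and `I` is the grid carbon intensity in kg CO₂eq/kWh — either a direct
regional value or the linear renewable/fossil mix
`I = s·I_ren + (1−s)·I_fos`.

Around that core the package provides:

- **`synthetic_cohort`** — seeded generation of slide cohorts with the
  statistical structure the accounting assumes (right-skewed pixel counts,
  bounded tissue/ROI fractions with roi ≤ tissue, and a concave
  pixels→bytes compression curve solved analytically to hit a target
  pixel–file-size correlation), plus tile-workload aggregation and cohort
  validation.
- **`power_accounting`** — trapezoidal integration of component-level power
  traces, normalisation to the 10⁷-tile reference workload, small/medium/
  large size-classing by minimum/median/maximum energy per task type, a
  log₁₀–log₁₀ OLS of energy on parameter count with a pairs bootstrap
  (used to extrapolate to a 540-billion-parameter multitask model), and
  piecewise-linear pruning curves.
- **`emission_model`** — scenario emissions (1-task, 2-task, 7-task,
  multitask) with percentile-bootstrap 95% CIs, sequestration equivalents
  (mature trees at 21.8 kg CO₂eq/yr; forest area via 7.6 Gt/yr over
  40.6 million km²), slide-scanner emissions, and reduction comparators
  including a pathomics workflow.
- **`extrapolation`** — scaling institute emissions to regions via
  cancer-case counts and the institute's total-to-cancer case ratio
  (cross-multiplication of proportions), with per-region grid intensities
  and forest fractions.
- **`projection`** — yearly emission paths 2023–2052 under four
  multiplicative drivers (renewable share, model complexity, hardware
  efficiency, case counts), each an anchored trajectory with seeded
  bootstrap bands; best/mean/worst paths and the forest-exceedance year.

Packaged fixture tables (model calibration, regions, driver anchors) are
synthetic stand-ins with realistic structure — marked as such in their
filenames — and are meant to be replaced by measured values for real
audits.

## Worked example

Calibration summary and a one-scenario estimate on the packaged demo
configuration (a synthetic 13-case breast/prostate cohort):

```
$ pathocarbon calibrate
classification  small   MobileNetV2             0.461 kWh/1e7 tiles
classification  medium  Xception                4.616 kWh/1e7 tiles
classification  large   NASNetLarge            24.834 kWh/1e7 tiles
segmentation    small   FPN                     2.243 kWh/1e7 tiles
segmentation    medium  DeepLabV3Plus           3.860 kWh/1e7 tiles
segmentation    large   AttentionUNet          12.908 kWh/1e7 tiles
log-log fit: slope 0.787, intercept -5.273 (30 models)
multitask estimate: 9201.6 kWh/1e7 tiles (95% CI 2792.2-35822.2)
```

The fitted slope says energy scales roughly as params^0.79; plugging a
540-billion-parameter model into the fit gives the multitask energy, whose
wide CI reflects the long extrapolation beyond the calibrated range.

```
$ pathocarbon estimate --scenario 1task --mode wsi --size large
one_task / wsi / large: 0.0106 t CO2eq (95% CI 0.01019-0.01101), 26.49 kWh, 1 trees
$ pathocarbon estimate --scenario 7task --mode tissue --size small
seven_task / tissue / small: 0.001245 t CO2eq (95% CI 0.001221-0.001268), 3.112 kWh, 1 trees
```

Running the largest classifier over every tile of the 13-case cohort for a
year emits about 10.6 kg CO₂eq; switching to seven small models on
tissue-containing tiles only is still an order of magnitude cheaper —
the data- and model-reduction effects compound.

`pathocarbon report --seed 7 --out out/` writes the full bundle:
`emissions.csv` (scenario × mode × size grid), `extrapolation.csv`
(per-region table), `projection.csv` (best/mean/worst paths to 2052),
`audit.json` (headline numbers plus a provenance block with the seed and
constants used) and `summary.md`.

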