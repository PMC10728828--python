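# Demo run configuration. Table paths left null fall back to the packaged
# synthetic fixtures; every value here is overridable.
tables:
  cohort: null        # null -> generate synthetically from the cohort block
  calibration: null   # null -> packaged model_calibration_synthetic.csv
  regions: null       # null -> packaged regions_synthetic.csv
  drivers: null       # null -> packaged driver_anchors_synthetic.csv

cohort:
  n_cases: {prostate: 5, breast: 8}
  target_size_pixel_corr: 0.58

tiling:
  tile_edge_px: 512

device: quadro_6000
intensity_kg_per_kwh: 0.40   # German grid, study year
noise_sd: 0.02
n_boot: 2000

anchor:
  cancer_cases: 4804
  total_cases: 40356

extrapolation_scenario: multitask
extrapolation_mode: tissue

scanner:
  n_slides: 237179
  power_w: 580.0
  minutes_per_slide: 1.0
  intensity_kg_per_kwh: 0.40
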