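# Run configuration reference

All `padsense` subcommands accept `--config config.yaml`; keys you supply are
merged over the defaults below, `--seed` overrides `seed`, and unknown or
ill-typed keys abort with exit code 2 listing every offending key path.  A
persisted configuration re-runs to identical outputs: every stochastic stage
derives its streams from `seed`.

```yaml
seed: 1                     # master seed for every stochastic stage
alpha: 0.05                 # two-tailed significance level for t tests

synth:                      # generative model (see docs/methods.md)
  receptor_color: [230.0, 200.0, 60.0]   # zone color at c = 0 (RGB, 0-255)
  paper_color: [250.0, 250.0, 245.0]     # background / full-fade color
  slope_m: 0.8              # response units per µmol/L
  conc_max: 100.0           # µmol/L, upper bound of the generative model
  noise_sd: 2.0             # per-pixel per-channel Gaussian SD
  illum_gradient: 0.02      # fractional horizontal illumination ramp
  zone_center: [32.0, 32.0] # (row, col) pixels
  zone_radius: 20.0         # pixels
  frame_size: 64            # pixels (square frame)
  device_rsd: 0.0377        # between-device response CV

roi:                        # extraction geometry
  mode: fixed-circle        # fixed-circle | auto-circle | full-frame
  center_row: 32.0
  center_col: 32.0
  radius_px: 20.0

calibration:
  range: [1.0, 100.0]       # linear range, µmol/L
  concentrations: [1.0, 20.0, 40.0, 60.0, 80.0, 100.0]
  n_replicates: 5
  n_blanks: 20              # blank pairs for the LOD's sigma_blank

reproducibility:
  concentration: 40.0       # µmol/L
  n_devices: 5

stability:
  n_days: 30
  stable_until_day: 20
  drift_rate: 0.08          # fractional response loss per day after breakpoint

optimization:               # single-parameter scan (e.g. analyte volume, µL)
  levels: [0.5, 1.0, 2.0, 3.0, 4.0]
  relative_profile: [0.55, 0.8, 1.0, 0.85, 0.6]
  n_replicates: 3

interference:
  analyte_conc: 40.0        # µmol/L
  ratios: [20.0, 50.0, 100.0, 500.0]    # [foreign]/[analyte], ascending
  interfering_effect: 0.08  # fractional response shift beyond the tolerance
  species_tolerance:        # generating tolerance limit per species
    Na+: 500
    K+: 500
    Ca2+: 500
    Fe3+: 500
    Glucose: 500
    Urea: 50
    SO3^2-: 50
    Cl-: 50
    I-: 20
    SCN-: 20
```

The method-comparison stage (`compare`, and the comparison block of `demo`)
takes its design — group structure, true concentrations, per-sample method
SDs, five determinations per method — from the bundled panel
(`padsense.datasets.load_method_comparison_panel`).
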