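# Default virtual pediatric population configuration.
# Growth table: bundled CSV of median weight/height by age and sex with
# log-normal CVs.  Ontogeny/GFR/MPPGL parameters are calibrated so that
# simulated per-kg clearance of a CYP3A4 substrate reproduces the
# age profile reported for such drugs: steep rise over the first weeks,
# peak above adult activity in infancy/early childhood, adult level by
# late adolescence.
schema_version: 1
growth_table: growth_reference.csv
ontogeny:
  fraction_at_birth: 0.05
  age50_years: 0.07
  hill: 1.2
  overshoot_amplitude: 0.65
  overshoot_rise_age50_years: 0.25
  overshoot_rise_hill: 2.8
  overshoot_fall_age50_years: 9.0
  overshoot_fall_hill: 8.0
gfr:
  adult_gfr_ml_min: 121.0
  pma50_weeks: 47.7
  hill: 3.4
  allometric_exponent: 0.75
  term_pma_weeks: 40.0
mppgl:
  intercept: 1.407
  linear: 0.0158
  quadratic: -0.00038
  cubic: 0.0000024
iiv:
  cyp3a4_abundance_cv: 0.35
  weight_height_correlation: 0.7
body: {}
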