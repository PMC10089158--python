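# Shared configuration for the numbered analysis drivers.
# A desk-scale synthetic study: 50 fires x 20 plots, the full starting
# model (all six postfire anomaly metrics, mean-deficit interactions).
seed: 20230306
outdir: results/pipeline
n_fires: 50
plots_per_fire: 20
random_intercept_sd: 0.7
fixed_coefficients:
  intercept: -4.0
  dist_seed_m: -0.004
  tree_cover_pct: 0.03
  rbr: -0.002
  time_since_fire: 0.10
  chili: -0.002
  mean_annual_deficit_mm: -0.004
  max_postfire_gs_deficit_z: -0.5
  min_postfire_gs_precip_z: 0.0
temp_trend_c_per_decade: 0.35
whc_mm: 150.0
latitude: 45.0
postfire_metrics:
- max_postfire_gs_deficit_z
- min_postfire_gs_deficit_z
- max_postfire_summer_vpd_z
- min_postfire_summer_vpd_z
- max_postfire_gs_precip_z
- min_postfire_gs_precip_z
mean_climate_metric: mean_annual_deficit_mm
quadratic_terms:
- time_since_fire
- dist_seed_m
use_disturbance: true
use_variety: true
cv_folds: 10
threshold_method: max_kappa
threshold_source: cv
periods:
- 1981-2000
- 2001-2020
- 2031-2050
pdp_draws: 1000
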