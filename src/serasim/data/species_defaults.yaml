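# Calibrated species parameter sets (units: m, m^2, kg, yr).
#
# e_dm pins the whole-tree mass-DBH log-log slope (= 1/e_dm) to published
# allometric values for each functional type: 2.54 silver fir, 2.48
# generalized conifer, 2.63 generalized angiosperm, 2.45 cryptomeria.
# The remaining rate constants are calibration products, tuned so that
# 1-ha monoculture runs show canopy closure, self-thinning toward a
# stable stocking, heights inside the 6-49 m envelope, and 100-yr
# volumes of a few hundred m^3/ha.  They are NOT field measurements.

abies_alba:
  c_juv: 48.0
  gamma_juv: 0.6666666666666666
  h_asym: 46.0
  k_mature: 2.2
  wood_density: 430.0
  c_dm: 0.040853
  e_dm: 0.39370078740157477   # 1/2.54
  c_lm: 0.066590
  e_lm: 0.75
  c_can: 5.5918
  e_can: 0.6
  g_eff: 0.78
  repro_height_frac: 0.20
  seeds_per_year: 1
  dispersal_radius: 14.0
  seedling_mass: 0.024
  seedling_mass_sigma: 0.3
  growth_sigma: 0.45
  mort_frac: 1.3
  persist_years: 1
  senescence_rate: 0.0
  senescence_power: 6.0

cryptomeria:
  c_juv: 48.0
  gamma_juv: 0.6666666666666666
  h_asym: 37.0
  k_mature: 3.4
  wood_density: 340.0
  c_dm: 0.041827
  e_dm: 0.40816326530612246   # 1/2.45
  c_lm: 0.066590
  e_lm: 0.75
  c_can: 5.5918
  e_can: 0.6
  g_eff: 0.62
  repro_height_frac: 0.35
  seeds_per_year: 1
  dispersal_radius: 12.0
  seedling_mass: 0.024
  seedling_mass_sigma: 0.3
  growth_sigma: 0.45
  mort_frac: 1.3
  persist_years: 1
  senescence_rate: 0.0
  senescence_power: 6.0

generic_gymnosperm:
  c_juv: 46.0
  gamma_juv: 0.6666666666666666
  h_asym: 38.0
  k_mature: 3.0
  wood_density: 450.0
  c_dm: 0.041004
  e_dm: 0.4032258064516129    # 1/2.48
  c_lm: 0.066590
  e_lm: 0.75
  c_can: 5.5918
  e_can: 0.6
  g_eff: 0.72
  repro_height_frac: 0.45
  seeds_per_year: 1
  dispersal_radius: 12.0
  seedling_mass: 0.024
  seedling_mass_sigma: 0.3
  growth_sigma: 0.45
  mort_frac: 1.3
  persist_years: 1
  senescence_rate: 0.0
  senescence_power: 6.0

generic_angiosperm:
  c_juv: 44.0
  gamma_juv: 0.6666666666666666
  h_asym: 24.0
  k_mature: 6.0
  wood_density: 600.0
  c_dm: 0.038994
  e_dm: 0.38022813688212925   # 1/2.63
  c_lm: 0.066590
  e_lm: 0.75
  c_can: 5.5918
  e_can: 0.6
  g_eff: 1.05
  repro_height_frac: 0.30
  seeds_per_year: 3
  dispersal_radius: 14.0
  seedling_mass: 0.024
  seedling_mass_sigma: 0.3
  growth_sigma: 0.45
  mort_frac: 1.5
  persist_years: 1
  senescence_rate: 0.0
  senescence_power: 6.0
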