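seed: 1
alphas:
- 0.05
- 0.1
edge_count: 100
rates_K_min:
- 0.5
- 1.0
- 2.0
exo_window_C:
- 82.0
- 140.0
melt_window_C:
- 140.5
- 157.0
conditions:
- name: annealed_-20C_40d
  kinetics:
    Ea_kJ_mol: 134.0
    lnA: 39.4102
    n: 4.7
    alpha0: 0.0001
  ratio_II_I: 7.4
  avrami:
    t10_min: 13.6
    n: 4.7
  pxrd_areas:
    6.8: 43
    16.1: 1000
    16.6: 267
    19.0: 437
    19.7: 64
- name: annealed_25C_40d
  kinetics:
    Ea_kJ_mol: 115.0
    lnA: 32.6858
    n: 4.1
    alpha0: 1.0e-05
  ratio_II_I: 5.4
  avrami:
    t10_min: 18.3
    n: 4.1
  pxrd_areas:
    6.8: 53
    16.1: 1000
    16.6: 287
    19.0: 396
    19.7: 156
isothermal:
  hold_temp_C: 100.0
  duration_min: 120.0
  dt_min: 0.01
  cp_amorphous: 2.1
  cp_crystal: 1.5
noise:
  dsc_mW_mg: 0.0005
  mdsc_J_gK: 0.002
  pxrd_counts: 2.0
  dissolution_ug_mL: 0.2
pxrd:
  grid:
  - 2.5
  - 40.0
  - 0.01
  fwhm_deg: 0.14
  background:
  - 60.0
  - -0.8
  form_labels:
    6.8: form I
    16.1: form II
    16.6: form I
    19.0: form II
    19.7: form I
dissolution:
  peak_time_h: 24.0
  c_max: 55.0
  c_final: 18.0
  first_point_bias: 0.9
  duration_h: 48.0
  dt_min: 10.0
  nominal_ug_mL: 40.0
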