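# Free doxorubicin, 50 mg m^-2 cohort of the same clinical trial;
# disposition parameters expressed as blood amounts (mg) using a 5 L
# blood volume.
drug:
  name: doxorubicin
  molar_mass_g_per_mol: 543.52   # free base
  payload_per_carrier: 1         # free small-molecule drug
pk:
  A_mg: 28.5
  B_mg: 1.1
  alpha_per_h: 11.6
  beta_per_h: 0.067
dose:
  mg_per_m2: 50.0
  bsa_m2: 1.8
  blood_volume_L: 5.0
model:
  epr_ratios: [0.0, 1.0e-1, 1.0e-2, 1.0e-3, 1.0e-4]
  back_ratios: [0.0, 10.0, 100.0, 1000.0]
  t_end_h: 48.0
  n_points: 400
  spacing: geometric
  t_min_h: 1.0e-3
architecture:
  tumor_volume_cm3: 1.0
  vessel_length_density_mm_per_mm3: 150.0
  segment_length_um: 100.0
  vessel_diameter_um: 30.0
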