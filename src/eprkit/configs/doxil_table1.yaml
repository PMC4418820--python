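# Pegylated liposomal doxorubicin (Doxil), 50 mg m^-2 cohort of a human
# clinical trial; disposition parameters expressed as blood amounts (mg)
# using a 5 L blood volume.
drug:
  name: Doxil
  molar_mass_g_per_mol: 543.52   # doxorubicin free base
  payload_per_carrier: 15000     # doxorubicin molecules per liposome
pk:
  A_mg: 34.5
  B_mg: 61.0
  alpha_per_h: 0.301
  beta_per_h: 0.015
dose:
  mg_per_m2: 50.0
  bsa_m2: 1.8
  blood_volume_L: 5.0
model:
  epr_ratios: [0.0, 1.0e-1, 1.0e-2, 1.0e-3, 1.0e-4]
  back_ratios: [0.0, 10.0, 100.0, 1000.0]
  t_end_h: 240.0
  n_points: 400
  spacing: geometric
  t_min_h: 1.0e-3
architecture:
  tumor_volume_cm3: 1.0
  vessel_length_density_mm_per_mm3: 150.0
  segment_length_um: 100.0
  vessel_diameter_um: 30.0
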