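# Infusion scenario presets: an unsupplemented baseline plus top-load
# (low volume) and exchange (large volume) infusion of a non-O2-carrying
# control, a 35:1 T-State polymerized Hb, and a 30:1 R-State polymerized
# Hb. c_hboc_mass in mg/mL, hboc_p50 in mm Hg, plasma_viscosity in cP;
# k_s scales the shear adaptation stimulus (NO scavenging by cell-free
# Hb). reference_bc holds published recalibrated boundary coefficients
# (p0 mm Hg, slope mm Hg/um) for orientation; they are recomputed by
# recalibrate_boundary at run time, not read from here.
baseline:
  hct: 0.45
  plasma_viscosity: 1.26
  c_hboc_mass: 0.0
  hboc_p50: null
  hboc_n: null
  k_s: 1.0
  reference_bc: {p0: 50.0, slope: 1.00}
topload_control:
  hct: 0.41
  plasma_viscosity: 1.26
  c_hboc_mass: 0.0
  hboc_p50: null
  hboc_n: null
  k_s: 1.0
  reference_bc: {p0: 49.6, slope: 1.01}
topload_t_state:
  hct: 0.41
  plasma_viscosity: 1.35
  c_hboc_mass: 8.0
  hboc_p50: 34.0
  hboc_n: 1.0
  k_s: 0.96
  reference_bc: {p0: 50.8, slope: 0.99}
topload_r_state:
  hct: 0.41
  plasma_viscosity: 1.32
  c_hboc_mass: 8.0
  hboc_p50: 1.3
  hboc_n: 1.0
  k_s: 0.95
  reference_bc: {p0: 49.6, slope: 1.01}
exchange_control:
  hct: 0.35
  plasma_viscosity: 1.26
  c_hboc_mass: 0.0
  hboc_p50: null
  hboc_n: null
  k_s: 1.0
  reference_bc: {p0: 46.7, slope: 1.06}
exchange_t_state:
  hct: 0.35
  plasma_viscosity: 1.51
  c_hboc_mass: 14.0
  hboc_p50: 34.0
  hboc_n: 1.0
  k_s: 0.95
  reference_bc: {p0: 49.0, slope: 1.02}
exchange_r_state:
  hct: 0.35
  plasma_viscosity: 1.47
  c_hboc_mass: 14.0
  hboc_p50: 1.3
  hboc_n: 1.0
  k_s: 0.90
  reference_bc: {p0: 46.7, slope: 1.06}
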