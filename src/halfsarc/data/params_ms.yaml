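model:
  model_kind: ms
  seed: 0
geometry:
  n_fil: 50
  n_xb: 76
  la: 1224.0
  lm: 825.0
  lb: 50.0
  crown_spacing: 14.3
mechanics:
  kappa_m: 2.0
  kappa_well: 48.0
  t0: 221.0
landscape:
  kt: 4.25
  h_kt: 5.8
  bias_kt: 8.0
  d: 5.5
  e_atp: 85.0
  nu_attempt: 10000000.0
attachment:
  f1: 9.0
  g1: 11.0
  g2: 480.0
  x_lim: 9.0
  x_dislodge: 20.0
  x_jitter: 2.5
  site_period: 11.0
on_off:
  k01_0: 750.0
  k10_0: 130.0
  m: 0.009122807017543859
  t_f: 0.036
  gamma: 1.0
engine:
  dt: 2.0e-06
  record_dt: 0.0002
  activation_ramp_ms: 1.0
  detach_to: auto
  onf_tension_mode: per_filament
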