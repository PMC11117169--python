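# Sample pipeline configuration (all fields optional; defaults shown)
seed: 0
network:
  seed: 0
  n_shunts: 10
  n_equivalent: 15
  thebesian_order_limit: 3
  thebesian_chamber: LA
heart:
  period: 0.6
  lv: {E_max: 2.0, E_min: 0.06, V0: 10.0, onset: 0.0, duration: 0.45}
  la: {E_max: 0.25, E_min: 0.12, V0: 5.0, onset: 0.80, duration: 0.35}
solver:
  n_beats: 8
  output_dt: 0.002
tracking:
  n_indicators: 1000
  replicates: 5
  duration_s: 600.0
  mode: steady
  release_orders: [1, 0, -1]
scenarios:
  names: [baseline, occlusion_only, sarp_nb, sarp_b]
  sarp_b_mean_mmhg: 63.9
  sarp_nb_mean_mmhg: 39.2
  pulse_mmhg: 30.0
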