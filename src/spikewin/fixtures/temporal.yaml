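# Tonotopic delay-line network learning frequency sweeps (times x10).
lif: {}
n_channels: 16
inter_channel_dt_ms: 10
repeat_gap_ms: 400
repeats: 50
neighbor_radius: 5
a_b1_w: 100.0
a_b2_w: 55.0
b1_b2_inh_w: -10.0
w_init_lo: 0.3
w_init_hi: 0.7
vg:
  j_c: 1.0
  tau_c: 100.0
  theta_v: -58.0
  theta_h_down: 0.0
  theta_h_up: 1.0e+9
  theta_l_down: 0.0
  theta_l_up: 1.0e+9
  a: 0.06
  b: 0.02
  alpha: 0.0
  beta: 0.0
  theta_w: 0.5
  w_min: 0.0
  w_max: 1.0
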