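# Voltage-gated rule demo: 3-spike bursts; the potentiation branch holds
# the membrane above theta_v with a steady auxiliary current and makes only
# the up-jump calcium-eligible; the depression branch keeps theta_v above
# any reachable depolarisation so the gate never opens and only the
# down-jump is eligible.
lif: {tau_syn: 1.0}
burst_spikes: 3
isi_ms: 2
margin: 0.02
w_max_factor: 1.6
a_factor: 0.05
b_factor: 0.05
theta_w_factor: 0.8
duration_ms: 1200
period_ms: 100
vg:
  j_c: 1.0
  tau_c: 150.0
  alpha: 0.0
  beta: 0.0
branch_potentiation:
  lif: {v_rest: -54.0, v_reset: -65.0}
  theta_v: -55.0
  theta_h_down: 0.0
  theta_h_up: 1.0e+9
  theta_l_down: 0.0
  theta_l_up: 0.0
branch_depression:
  theta_v: -50.2
  theta_h_down: 0.0
  theta_h_up: 0.0
  theta_l_down: 0.0
  theta_l_up: 1.0e+9
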