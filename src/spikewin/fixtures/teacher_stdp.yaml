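# Pre-post pairing with a teacher signal (10 ms lag).
lif: {}
pop_size: 10
lag_ms: 10
burst_period_ms: 150
burst_rate_hz: 350.0
burst_ms: 20
noise_hz: 2.0
phase_pre: [0, 1000]
phase_pair: [1500, 3000]
phase_test: [3500, 4500]
duration_ms: 4500
drive_w: 35.0
noise_w: 2.0
connect_p: 0.5
w_init: 0.6
stdp:
  a_plus: 1.2
  a_minus: 0.6
  tau_plus: 20.0
  tau_minus: 20.0
  w_min: 0.0
  w_max: 16.0
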