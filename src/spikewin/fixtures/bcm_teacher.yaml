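# BCM potentiation with a teaching signal.
lif: {}
pop_size: 5
duration_ms: 1800
teacher_on_ms: 600
teacher_off_ms: 1200
stim_rate_hz: 80.0
teacher_rate_hz: 150.0
teacher_w: 55.0
w_init: 5.0
bcm:
  delta: 1.0e-4
  epsilon: 0.0
  theta_ema: 0.1
  rate_lp: 1.0
  w_min: 0.0
  w_max: 55.0
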