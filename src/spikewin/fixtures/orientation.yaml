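# Orientation selectivity under BCM with static lateral inhibition.
# The fast-tracking threshold EMA penalises a neuron's second-strongest
# orientation, and the weak background drive keeps suppressed outputs'
# BCM state live so every bar eventually finds an owner.
lif: {r_m: 6.0}
grid: 16
n_outputs: 4
train_angles: [0, 45, 90, 135]
present_ms: 1000
repetitions: 80
total_rate_hz: 1000.0
tuning_step_deg: 10
tuning_present_ms: 1000
max_delay_ms: 8
lateral_w: -9.0
w_init_lo: 0.35
w_init_hi: 0.65
noise_rate_hz: 6.0
noise_w: 20.0
bcm:
  delta: 1.4e-4
  epsilon: 0.005
  theta_ema: 0.3
  rate_lp: 0.8
  w_min: 0.0
  w_max: 1.5
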