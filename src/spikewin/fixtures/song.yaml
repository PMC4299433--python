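# Balanced excitation: 1000 Poisson inputs at 20 Hz onto one neuron,
# depression-biased additive STDP splits weights into weak and strong.
lif: {r_m: 2.0}
n_inputs: 1000
input_rate_hz: 20.0
duration_ms: 300000
w_init_lo: 0.3
w_init_hi: 0.7
stdp:
  a_plus: 0.01
  a_minus: 0.011
  tau_plus: 20.0
  tau_minus: 20.0
  w_min: 0.0
  w_max: 1.0
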