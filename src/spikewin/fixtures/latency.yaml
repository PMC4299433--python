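# 10 sequential inputs at 2 ms spacing; potentiation-dominant STDP reduces
# first-spike latency; w0 calibrated so all 10 inputs are needed initially.
lif: {tau_syn: 1.0}
n_inputs: 10
isi_ms: 2
margin: 0.02
w_max_factor: 5.5
a_plus_factor: 0.05
tau_plus: 20.0
tau_minus: 20.0
duration_ms: 3000
period_ms: 50
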