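# Single-input 3-spike burst potentiation demo.
# w0 is calibrated at run time from the closed-form LIF response so that
# exactly burst_spikes inputs at isi_ms spacing first cross threshold.
lif: {tau_syn: 1.0}
burst_spikes: 3
isi_ms: 2
margin: 0.02
w_max_factor: 1.6
a_plus_factor: 0.05
tau_plus: 20.0
tau_minus: 20.0
duration_ms: 800
period_ms: 50
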