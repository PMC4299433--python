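# Minimal example: 20 Poisson sources onto 2 LIF neurons through a plastic
# STDP projection; weights are written back once per 128 ms window.
runtime:
  duration_ms: 2000
  seed: 1
  window_ms: 128
  bin_ms: 2
  snapshot_weights: boundaries
populations:
  - name: inputs
    size: 20
    model: poisson
    rate: 40.0
  - name: cells
    size: 2
    model: lif
    params: {v_rest: -65.0, v_thresh: -50.0, tau_m: 20.0, tau_syn: 5.0}
projections:
  - name: feedforward
    source: inputs
    target: cells
    connectivity: {kind: all-to-all}
    weight: {uniform: [0.5, 1.5]}
    delay: 2
    plastic: true
    rule:
      name: stdp_trace
      a_plus: 0.01
      a_minus: 0.012
      tau_plus: 20.0
      tau_minus: 20.0
      w_min: 0.0
      w_max: 3.0
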