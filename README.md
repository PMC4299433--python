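# spikewin

A spiking neural network simulator built around *windowed, batched synaptic
plasticity*: the 1 ms neural kernel and the weight-update machinery are
decoupled, with spike histories stored as double-buffered 2 ms-resolution
bitmaps over 128 ms windows and all plastic weights updated by a row-walking
pass once per window.  Three weight-update rules plug into the same pass:

- **trace-based STDP** — all-to-all double-exponential pairing computed from
  carried pre/post traces, with pre spike times shifted by the synaptic
  delay before comparison (delays are reintroduced at the post-synaptic end);
- **BCM** — rate-based Hebbian rule with a sliding modification threshold
  (EMA of the post rate) applied once per window;
- **voltage-gated bistable STDP** — pre-spike-triggered jumps gated by a
  per-millisecond membrane-potential bitmap and a calcium trace, with drift
  toward one of two stable weight values between events.

A write-back ledger counts one row write-back per window (batched mode) or
one per pre spike (deferred-event accounting) for comparison: a 1000 ms run
gives 8 batched write-backs per row versus 24 for a 24 Hz pre neuron.

## Layout

```
src/spikewin/
  engine.py        1 ms LIF kernel, delays/ring buffers, network, recordings
  framework.py     spike windows, double buffering, plasticity pass, ledger
  rules.py         the three plasticity rules + row-level functional forms
  stimuli.py       Poisson/teacher/oriented-bar/frequency-sweep generators
  experiments.py   scripted experiment reproductions + metrics
  cli_io/          config schema, file writers, command-line interface
  fixtures/        versioned parameter fixtures for every experiment
```

## CLI

```sh
spikewin validate --config examples/net.yaml
spikewin simulate --config examples/net.yaml --seed 1 --out out/
spikewin run-experiment song --seed 1 --out out/song
```

Experiments: `potentiation`, `latency`, `teacher_stdp`, `song`,
`bcm_teacher`, `orientation`, `vg_demo`, `temporal`.  Each writes spike
rasters (`spikes_<pop>.csv`), optional membrane traces, weight snapshots
(`weights_<proj>_<t>.txt`), write-back ledgers, `metrics.json` and a
self-describing `run_manifest.json`.  All outputs are plain text and
byte-identical across reruns with the same seed.

A config is a YAML file with `runtime`, `populations` (lif / poisson /
spike_source) and `projections` (one-to-one, all-to-all or Bernoulli
connectivity; plastic projections name a rule `stdp_trace | bcm | vg_stdp`
plus its flat parameter table) — see `tests/test_cli.py` for a complete
example.

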