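"""Scripted reproductions of classical plasticity experiments.

Each experiment builds a small network from a versioned fixture (YAML files
under ``spikewin/fixtures``), runs it deterministically from a single seed,
and computes its analysis metrics from the recordings and weight snapshots
alone.  Initial weights for the worked examples are not magic numbers: they
are calibrated from the closed-form LIF response so that "n input spikes
just reach threshold" holds by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import yaml

from . import stimuli
from .engine import (
    LIFParams,
    Network,
    Population,
    Projection,
    RecordingSet,
    Simulator,
    connect,
    rng_stream,
)
from .rules import make_rule

__all__ = [
    "ExperimentResult",
    "TuningCurve",
    "load_fixture",
    "lif_response_trajectory",
    "calibrate_burst_weight",
    "spikes_needed",
    "spikes_to_fire",
    "run_potentiation_experiment",
    "run_latency_experiment",
    "run_teacher_experiment",
    "run_song_experiment",
    "run_bcm_teacher_experiment",
    "run_orientation_experiment",
    "run_vg_experiment",
    "run_temporal_experiment",
    "run_experiment",
    "EXPERIMENTS",
]


@dataclass
class ExperimentResult:
    name: str
    seed: int
    recordings: RecordingSet
    weight_snapshots: dict
    metrics: dict


@dataclass
class TuningCurve:
    """Per-output-neuron mean firing rate versus stimulus angle."""

    angles: np.ndarray          # degrees
    rates: np.ndarray           # (n_angles, n_neurons) Hz

    def preferred_angles(self) -> np.ndarray:
        return self.angles[np.argmax(self.rates, axis=0)]


def load_fixture(name: str) -> dict:
    """Load an experiment's parameter fixture shipped with the package."""
    text = resources.files("spikewin.fixtures").joinpath(f"{name}.yaml").read_text()
    return yaml.safe_load(text)


def _lif_from(params: dict) -> LIFParams:
    return LIFParams(**params) if params else LIFParams()


# --------------------------------------------------------------------------
# closed-form calibration
# --------------------------------------------------------------------------


def lif_response_trajectory(
    params: LIFParams, arrival_times: Sequence[int], horizon: int
) -> np.ndarray:
    """Threshold-free membrane deviation from baseline for unit-weight
    spikes arriving at ``arrival_times``, using the engine's exact per-step
    update.  Element ``t`` is the deviation at the end of step ``t`` —
    the value the threshold test sees."""
    a, b, c = params.step_coefficients()
    arrivals = np.zeros(horizon)
    for t in arrival_times:
        if 0 <= t < horizon:
            arrivals[int(t)] += 1.0
    u = np.zeros(horizon)
    v = 0.0
    i_syn = 0.0
    for t in range(horizon):
        i0 = i_syn + arrivals[t]
        v = v * a + params.r_m * i0 * c
        i_syn = i0 * b
        u[t] = v
    return u


def _per_spike_maxima(u: np.ndarray, arrival_times: Sequence[int]) -> np.ndarray:
    """m_k = max deviation between the k-th arrival and the next one
    (the last interval runs to the end of the trajectory)."""
    arr = list(arrival_times)
    edges = arr + [len(u)]
    return np.array([u[edges[k]: edges[k + 1]].max() for k in range(len(arr))])


def calibrate_burst_weight(
    params: LIFParams,
    n_spikes: int,
    isi_ms: int = 2,
    margin: float = 0.02,
    v_offset: float = 0.0,
) -> float:
    """Weight w0 such that a burst of ``n_spikes`` at ``isi_ms`` spacing
    first crosses threshold exactly at the n-th spike (closed-form LIF
    construction; ``margin`` keeps the crossing strict).

    ``v_offset`` shifts the effective baseline (e.g. a steady depolarising
    current), reducing the distance to threshold.
    """
    theta_rel = params.v_thresh - params.v_rest - v_offset
    if theta_rel <= 0:
        raise ValueError("baseline must sit below threshold")
    arrivals = [k * isi_ms for k in range(n_spikes)]
    horizon = arrivals[-1] + int(5 * params.tau_m) + 1
    u = lif_response_trajectory(params, arrivals, horizon)
    m = _per_spike_maxima(u, arrivals)
    w0 = theta_rel * (1.0 + margin) / m[n_spikes - 1]
    if n_spikes > 1 and w0 * m[n_spikes - 2] >= theta_rel:
        raise ValueError(
            "cannot calibrate: n-1 spikes already reach threshold at this margin"
        )
    return float(w0)


def spikes_needed(
    params: LIFParams,
    weight: float,
    n_spikes: int,
    isi_ms: int = 2,
    v_offset: float = 0.0,
) -> Optional[int]:
    """Closed-form count of burst spikes needed to reach threshold at
    weight ``weight``; None if the full burst never crosses."""
    theta_rel = params.v_thresh - params.v_rest - v_offset
    arrivals = [k * isi_ms for k in range(n_spikes)]
    horizon = arrivals[-1] + int(5 * params.tau_m) + 1
    u = lif_response_trajectory(params, arrivals, horizon)
    m = _per_spike_maxima(u, arrivals)
    hits = np.flatnonzero(weight * m >= theta_rel)
    return int(hits[0]) + 1 if hits.size else None


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

NO_SPIKE = "no-spike"


def spikes_to_fire(
    input_times: np.ndarray,
    post_times: np.ndarray,
    pattern_onsets: Sequence[int],
    period: int,
):
    """Per-presentation count of input spikes preceding the first post
    spike; the sentinel ``"no-spike"`` marks presentations where the post
    neuron never fired.  An input emitted in the same millisecond as the
    post spike is not counted: with delays >= 1 ms it cannot have
    contributed to it."""
    input_times = np.asarray(input_times)
    post_times = np.asarray(post_times)
    out = []
    for onset in pattern_onsets:
        post_in = post_times[(post_times >= onset) & (post_times < onset + period)]
        if post_in.size == 0:
            out.append(NO_SPIKE)
            continue
        first = post_in[0]
        out.append(int(np.count_nonzero((input_times >= onset) & (input_times < first))))
    return out


def bimodality(weights: np.ndarray, w_min: float, w_max: float, frac: float = 0.1) -> float:
    """Fraction of weights within ``frac`` of either bound."""
    span = w_max - w_min
    w = np.asarray(weights)
    return float(np.mean((w <= w_min + frac * span) | (w >= w_max - frac * span)))


def weight_asymmetry(matrix: np.ndarray) -> float:
    """(sum below-diagonal - sum above-diagonal) / total, for a pre x post
    channel weight matrix (pre index < post index counts as 'below')."""
    lower = np.triu(matrix, k=1).sum()   # pre < post
    upper = np.tril(matrix, k=-1).sum()  # pre > post
    total = matrix.sum()
    return float((lower - upper) / total) if total > 0 else 0.0


# --------------------------------------------------------------------------
# Worked examples: burst potentiation and latency reduction
# --------------------------------------------------------------------------


def _burst_pattern_network(
    lif: LIFParams,
    n_inputs: int,
    isi: int,
    period: int,
    duration: int,
    rule,
    w0: float,
    delay: int = 1,
):
    """n_inputs sources firing ``isi`` ms apart (input k at onset + k*isi),
    pattern repeated every ``period`` ms, all-to-all onto one LIF neuron."""
    onsets = np.arange(0, duration - n_inputs * isi, period)
    trains = [onsets + k * isi for k in range(n_inputs)]
    src = Population("in", n_inputs, kind="source", trains=trains)
    out = Population("out", 1, kind="lif", params=lif, record_v=True)
    proj = connect("plastic", src, out, "all-to-all", weight=w0, delay=delay,
                   plastic=True, rule=rule)
    return Network([src, out], [proj]), onsets


def run_potentiation_experiment(seed: int = 0, **overrides) -> ExperimentResult:
    """Single input repeating a 3-spike burst through one plastic synapse:
    potentiation saturates the weight at 1.6 w0 so the post neuron fires
    after 2 instead of 3 input spikes."""
    cfg = {**load_fixture("potentiation"), **overrides}
    lif = _lif_from(cfg.get("lif"))
    n_b, isi = cfg["burst_spikes"], cfg["isi_ms"]
    w0 = calibrate_burst_weight(lif, n_b, isi, margin=cfg["margin"])
    w_max = cfg["w_max_factor"] * w0
    rule = make_rule(
        "stdp_trace",
        a_plus=cfg["a_plus_factor"] * w0, a_minus=0.0,
        tau_plus=cfg["tau_plus"], tau_minus=cfg["tau_minus"],
        w_min=0.0, w_max=w_max,
    )
    # one source neuron emitting the whole burst
    duration, period = cfg["duration_ms"], cfg["period_ms"]
    onsets = np.arange(0, duration - n_b * isi, period)
    train = np.sort(np.concatenate([onsets + k * isi for k in range(n_b)]))
    src = Population("in", 1, kind="source", trains=[train])
    out = Population("out", 1, kind="lif", params=lif, record_v=True)
    proj = connect("plastic", src, out, "all-to-all", weight=w0, delay=1,
                   plastic=True, rule=rule)
    net = Network([src, out], [proj])
    sim = Simulator(net, snapshot_weights="boundaries")
    rec = sim.run(duration, seed=seed)
    stf = spikes_to_fire(rec.spike_times("in"), rec.spike_times("out"), onsets, period)
    sat_t = next(
        (t for t, w in rec.weight_snapshots["plastic"] if w[0] >= w_max * (1 - 1e-9)),
        None,
    )
    metrics = {
        "w0": w0,
        "w_max": w_max,
        "spikes_to_fire": stf,
        "initial_spikes_to_fire": stf[0],
        "final_spikes_to_fire": stf[-1],
        "saturation_time_ms": sat_t,
        "final_weight": float(proj.weights[0]),
    }
    return ExperimentResult("potentiation", seed, rec, rec.weight_snapshots, metrics)


def run_latency_experiment(seed: int = 0, **overrides) -> ExperimentResult:
    """10 inputs firing 2 ms apart onto one neuron; repeated presentation
    under potentiation-dominant STDP moves the first post spike toward the
    pattern onset (10 spikes needed initially, 2 after convergence)."""
    cfg = {**load_fixture("latency"), **overrides}
    lif = _lif_from(cfg.get("lif"))
    n_in, isi = cfg["n_inputs"], cfg["isi_ms"]
    w0 = calibrate_burst_weight(lif, n_in, isi, margin=cfg["margin"])
    w_max = cfg["w_max_factor"] * w0
    rule = make_rule(
        "stdp_trace",
        a_plus=cfg["a_plus_factor"] * w0, a_minus=0.0,
        tau_plus=cfg["tau_plus"], tau_minus=cfg["tau_minus"],
        w_min=0.0, w_max=w_max,
    )
    net, onsets = _burst_pattern_network(
        lif, n_in, isi, cfg["period_ms"], cfg["duration_ms"], rule, w0
    )
    rec = Simulator(net, snapshot_weights="boundaries").run(cfg["duration_ms"], seed=seed)
    in_t = rec.spike_times("in")
    out_t = rec.spike_times("out")
    stf = spikes_to_fire(in_t, out_t, onsets, cfg["period_ms"])
    latencies = []
    for onset in onsets:
        hits = out_t[(out_t >= onset) & (out_t < onset + cfg["period_ms"])]
        latencies.append(int(hits[0] - onset) if hits.size else None)
    metrics = {
        "w0": w0,
        "w_max": w_max,
        "spikes_to_fire": stf,
        "initial_spikes_to_fire": stf[0],
        "final_spikes_to_fire": stf[-1],
        "latency_series": latencies,
        "mean_final_weight": float(np.mean(rec.weight_snapshots["plastic"][-1][1])),
    }
    return ExperimentResult("latency", seed, rec, rec.weight_snapshots, metrics)


# --------------------------------------------------------------------------
# STDP teacher pairing
# --------------------------------------------------------------------------


def run_teacher_experiment(seed: int = 0, **overrides) -> ExperimentResult:
    """Pre-post pairing with a teacher: stimulus and target populations are
    burst-driven with a 10 ms lag during the pairing phase; afterwards the
    potentiated stimulus->target synapses drive the targets alone."""
    cfg = {**load_fixture("teacher_stdp"), **overrides}
    lif = _lif_from(cfg.get("lif"))
    n = cfg["pop_size"]
    rng = rng_stream(seed, "teacher:protocol")
    lag = cfg["lag_ms"]

    def onsets(t0, t1):
        return np.arange(t0, t1, cfg["burst_period_ms"])

    pre_onsets = np.concatenate(
        [onsets(*cfg["phase_pre"]), onsets(*cfg["phase_pair"]), onsets(*cfg["phase_test"])]
    )
    pair_onsets = onsets(*cfg["phase_pair"])
    stim_trains = [
        stimuli.burst_times(pre_onsets, rng_stream(seed, f"teacher:stim{i}"),
                            cfg["burst_rate_hz"], cfg["burst_ms"])
        for i in range(n)
    ]
    teach_trains = [
        stimuli.burst_times(pair_onsets + lag, rng_stream(seed, f"teacher:teach{i}"),
                            cfg["burst_rate_hz"], cfg["burst_ms"])
        for i in range(n)
    ]
    noise = stimuli.PoissonSpec(cfg["noise_hz"], 0, cfg["duration_ms"], n)

    stim_src = Population("stim_src", n, kind="source", trains=stim_trains)
    teach_src = Population("teach_src", n, kind="source", trains=teach_trains)
    noise_a = Population(
        "noise_stim", n, kind="source",
        stimulus=lambda r, d: stimuli.poisson_train(noise, r),
    )
    noise_b = Population(
        "noise_target", n, kind="source",
        stimulus=lambda r, d: stimuli.poisson_train(noise, r),
    )
    stim = Population("stimulus", n, kind="lif", params=lif)
    target = Population("target", n, kind="lif", params=lif)
    rule = make_rule("stdp_trace", **cfg["stdp"])
    projs = [
        connect("drive_stim", stim_src, stim, "one-to-one", cfg["drive_w"], 1),
        connect("drive_target", teach_src, target, "one-to-one", cfg["drive_w"], 1),
        connect("noise_stim", noise_a, stim, "one-to-one", cfg["noise_w"], 1),
        connect("noise_target", noise_b, target, "one-to-one", cfg["noise_w"], 1),
        connect("plastic", stim, target, "bernoulli", cfg["w_init"], 1,
                p=cfg["connect_p"], rng=rng_stream(seed, "connectivity"),
                plastic=True, rule=rule),
    ]
    net = Network([stim_src, teach_src, noise_a, noise_b, stim, target], projs)
    rec = Simulator(net).run(cfg["duration_ms"], seed=seed)

    def pop_rate(pop, t0, t1):
        t, _ = rec.spikes[pop]
        nsp = np.count_nonzero((t >= t0) & (t < t1))
        return 1000.0 * nsp / (t1 - t0) / n

    r_pre = pop_rate("target", *cfg["phase_pre"])
    r_test = pop_rate("target", *cfg["phase_test"])
    metrics = {
        "target_rate_before_hz": r_pre,
        "target_rate_after_hz": r_test,
        "mean_weight_initial": float(cfg["w_init"]),
        "mean_weight_final": float(np.mean(projs[-1].weights)),
        "potentiated": bool(r_test > max(2.0 * r_pre, r_pre + 2.0)),
    }
    return ExperimentResult("teacher_stdp", seed, rec, rec.weight_snapshots, metrics)


# --------------------------------------------------------------------------
# balanced excitation (bimodal weight distribution)
# --------------------------------------------------------------------------


def run_song_experiment(seed: int = 0, **overrides) -> ExperimentResult:
    """1000 uncorrelated 20 Hz Poisson inputs onto a single neuron under
    depression-biased additive STDP: weights split into weak and strong
    groups."""
    cfg = {**load_fixture("song"), **overrides}
    lif = _lif_from(cfg.get("lif"))
    n = cfg["n_inputs"]
    duration = cfg["duration_ms"]
    spec = stimuli.PoissonSpec(cfg["input_rate_hz"], 0, duration, n)
    src = Population(
        "in", n, kind="source",
        stimulus=lambda r, d: stimuli.poisson_train(spec, r),
    )
    out = Population("out", 1, kind="lif", params=lif)
    rule = make_rule("stdp_trace", **cfg["stdp"])
    w_rng = rng_stream(seed, "weights")
    w_init = w_rng.uniform(cfg["w_init_lo"], cfg["w_init_hi"], size=n)
    proj = connect("plastic", src, out, "all-to-all",
                   weight=w_init, delay=1, plastic=True, rule=rule)
    net = Network([src, out], [proj])
    rec = Simulator(net).run(duration, seed=seed)
    w_min, w_max = rule.w_min, rule.w_max
    w_final = proj.weights
    bins = np.linspace(w_min, w_max, 51)
    metrics = {
        "bimodality_initial": bimodality(w_init, w_min, w_max),
        "bimodality_final": bimodality(w_final, w_min, w_max),
        "sum_w_initial": float(w_init.sum()),
        "sum_w_final": float(w_final.sum()),
        "hist_bins": bins.tolist(),
        "hist_initial": np.histogram(w_init, bins)[0].tolist(),
        "hist_final": np.histogram(w_final, bins)[0].tolist(),
        "post_rate_hz": rec.rate("out", 0),
    }
    return ExperimentResult("song", seed, rec, rec.weight_snapshots, metrics)


# --------------------------------------------------------------------------
# BCM: teacher potentiation and orientation selectivity
# --------------------------------------------------------------------------


def run_bcm_teacher_experiment(seed: int = 0, **overrides) -> ExperimentResult:
    """BCM potentiation with a teaching signal: stimulus alone is too weak,
    pairing with a teacher drives the target above its sliding threshold
    and potentiates the stimulus->target weights."""
    cfg = {**load_fixture("bcm_teacher"), **overrides}
    lif = _lif_from(cfg.get("lif"))
    n = cfg["pop_size"]
    duration = cfg["duration_ms"]
    t_teach0, t_teach1 = cfg["teacher_on_ms"], cfg["teacher_off_ms"]
    stim_spec = stimuli.PoissonSpec(cfg["stim_rate_hz"], 0, duration, n)
    teach_spec = stimuli.PoissonSpec(cfg["teacher_rate_hz"], t_teach0, t_teach1, n)
    stim_src = Population(
        "stim_src", n, kind="source",
        stimulus=lambda r, d: stimuli.poisson_train(stim_spec, r),
    )
    teach_src = Population(
        "teach_src", n, kind="source",
        stimulus=lambda r, d: stimuli.poisson_train(teach_spec, r),
    )
    target = Population("target", n, kind="lif", params=lif)
    rule = make_rule("bcm", **cfg["bcm"])
    projs = [
        connect("plastic", stim_src, target, "one-to-one", cfg["w_init"], 1,
                plastic=True, rule=rule),
        connect("teach", teach_src, target, "one-to-one", cfg["teacher_w"], 1),
    ]
    net = Network([stim_src, teach_src, target], projs)
    rec = Simulator(net).run(duration, seed=seed)
    t, _ = rec.spikes["target"]

    def rate(t0, t1):
        return 1000.0 * np.count_nonzero((t >= t0) & (t < t1)) / (t1 - t0) / n

    metrics = {
        "rate_before_hz": rate(0, t_teach0),
        "rate_during_hz": rate(t_teach0, t_teach1),
        "rate_after_hz": rate(t_teach1, duration),
        "mean_weight_final": float(np.mean(projs[0].weights)),
        "w_init": cfg["w_init"],
    }
    metrics["potentiated"] = bool(
        metrics["rate_after_hz"] > max(2.0 * metrics["rate_before_hz"], 2.0)
    )
    return ExperimentResult("bcm_teacher", seed, rec, rec.weight_snapshots, metrics)


def _orientation_network(cfg, seed, weights, plastic, trains, noise_tag="noise"):
    grid = cfg["grid"]
    n_in = grid * grid
    n_out = cfg["n_outputs"]
    lif = _lif_from(cfg.get("lif"))
    src = Population("in", n_in, kind="source", trains=trains)
    out = Population("out", n_out, kind="lif", params=lif)
    rule = make_rule("bcm", **cfg["bcm"]) if plastic else None
    d_rng = rng_stream(seed, "delays")
    delays = d_rng.integers(1, cfg["max_delay_ms"] + 1, size=n_in * n_out)
    projs = [
        connect("plastic", src, out, "all-to-all", weights, delays,
                plastic=plastic, rule=rule)
    ]
    pops = [src, out]
    if cfg.get("noise_rate_hz", 0) > 0:
        # independent background drive so suppressed outputs keep firing
        # occasionally and their BCM state stays live
        rate = float(cfg["noise_rate_hz"])
        noise = Population(
            noise_tag, n_out, kind="source",
            stimulus=lambda r, d, rate=rate: stimuli.poisson_train(
                stimuli.PoissonSpec(rate, 0, max(d, 1), n_out), r),
        )
        projs.append(connect("noise", noise, out, "one-to-one", cfg["noise_w"], 1))
        pops.append(noise)
    if cfg["lateral_w"] != 0:
        pre_l, post_l = np.nonzero(~np.eye(n_out, dtype=bool))
        projs.append(
            Projection("lateral", out, out, pre_l, post_l,
                       np.full(len(pre_l), float(cfg["lateral_w"])),
                       np.ones(len(pre_l), dtype=np.int64))
        )
    return Network(pops, projs), projs[0]


def run_orientation_experiment(seed: int = 0, **overrides) -> ExperimentResult:
    """Emergence of orientation selectivity under BCM with lateral
    inhibition: 16x16 Poisson inputs encoding oriented bars project onto 4
    output neurons; after 80 one-second presentations each output prefers a
    distinct training orientation (tuning measured in 10 degree steps)."""
    cfg = {**load_fixture("orientation"), **overrides}
    grid = cfg["grid"]
    n_in = grid * grid
    angles = cfg["train_angles"]
    present_ms = cfg["present_ms"]
    reps = cfg["repetitions"]
    bar_rng = rng_stream(seed, "bars")
    bars = {a: stimuli.bar_image(a, bar_rng, grid=grid, total_rate=cfg["total_rate_hz"])
            for a in angles}
    # block-shuffled presentation order (each block is a permutation)
    order_rng = rng_stream(seed, "order")
    order = np.concatenate(
        [order_rng.permutation(len(angles)) for _ in range(reps // len(angles))]
    )
    train_parts: list[list[np.ndarray]] = [[] for _ in range(n_in)]
    stim_rng = rng_stream(seed, "stimulus:bars")
    for k, ai in enumerate(order):
        trains_k = stimuli.bar_poisson_trains(
            bars[angles[ai]], present_ms, stim_rng, start=k * present_ms
        )
        for i in range(n_in):
            train_parts[i].append(trains_k[i])
    trains = [np.concatenate(p) for p in train_parts]
    duration = len(order) * present_ms

    w_rng = rng_stream(seed, "weights")
    w_init = w_rng.uniform(cfg["w_init_lo"], cfg["w_init_hi"], size=n_in * cfg["n_outputs"])
    net, proj = _orientation_network(cfg, seed, w_init, True, trains)
    rec = Simulator(net).run(duration, seed=seed)
    learned = proj.weights.copy()

    # tuning curves with plasticity off and learned weights frozen
    test_angles = np.arange(0, 180, cfg["tuning_step_deg"])
    test_ms = cfg["tuning_present_ms"]
    t_rng = rng_stream(seed, "stimulus:tuning")
    rates_out = np.zeros((len(test_angles), cfg["n_outputs"]))
    for k, ang in enumerate(test_angles):
        bar = stimuli.bar_image(float(ang), rng_stream(seed, f"tuning_bar:{ang}"),
                                grid=grid, total_rate=cfg["total_rate_hz"])
        t_trains = stimuli.bar_poisson_trains(bar, test_ms, t_rng)
        t_net, _ = _orientation_network(cfg, seed, learned.copy(), False, t_trains)
        t_rec = Simulator(t_net).run(test_ms, seed=seed)
        _, ids = t_rec.spikes["out"]
        counts = np.bincount(ids, minlength=cfg["n_outputs"])
        rates_out[k] = counts * 1000.0 / test_ms
    curve = TuningCurve(test_angles.astype(float), rates_out)
    pref = curve.preferred_angles()
    # map each preferred angle onto the nearest training orientation (mod 180)
    train_mod = np.asarray(angles, dtype=float) % 180.0
    diffs = np.abs(pref[:, None] - train_mod[None, :])
    diffs = np.minimum(diffs, 180.0 - diffs)
    assigned = np.argmin(diffs, axis=1)
    metrics = {
        "preferred_angles_deg": pref.tolist(),
        "assigned_orientations": [float(train_mod[i]) for i in assigned],
        "is_permutation": bool(len(set(assigned.tolist())) == len(angles)),
        "tuning_angles_deg": test_angles.tolist(),
        "tuning_rates_hz": rates_out.tolist(),
        "lateral_w": cfg["lateral_w"],
    }
    res = ExperimentResult("orientation", seed, rec, rec.weight_snapshots, metrics)
    res.metrics["receptive_fields"] = (
        learned.reshape(n_in, cfg["n_outputs"]).T.tolist()
    )
    return res


# --------------------------------------------------------------------------
# voltage-gated STDP: potentiation/depression demo and temporal patterns
# --------------------------------------------------------------------------


def run_vg_experiment(seed: int = 0, branch: str = "potentiation", **overrides) -> ExperimentResult:
    """Voltage-gated rule demo: repeated 3-spike bursts through one plastic
    synapse.  In the potentiation branch an auxiliary depolarising current
    keeps V above theta_V, the weight jumps up by ``a`` per arrival and the
    neuron ends up firing after 2 spikes; in the depression branch V stays
    below theta_V, the weight falls and the neuron stops firing."""
    cfg = {**load_fixture("vg_demo"), **overrides}
    if branch not in ("potentiation", "depression"):
        raise ValueError("branch must be potentiation or depression")
    branch_cfg = dict(cfg[f"branch_{branch}"])
    lif_kw = {**(cfg.get("lif") or {}), **branch_cfg.pop("lif", {})}
    lif = _lif_from(lif_kw)
    v_off = lif.r_m * lif.i_offset
    n_b, isi = cfg["burst_spikes"], cfg["isi_ms"]
    w0 = calibrate_burst_weight(lif, n_b, isi, margin=cfg["margin"], v_offset=v_off)
    w_max = cfg["w_max_factor"] * w0
    vg = {**cfg["vg"], **branch_cfg}
    vg.update(
        a=cfg["a_factor"] * w0, b=cfg["b_factor"] * w0,
        w_min=0.0, w_max=w_max, theta_w=cfg["theta_w_factor"] * w0,
    )
    rule = make_rule("vg_stdp", **vg)
    duration, period = cfg["duration_ms"], cfg["period_ms"]
    onsets = np.arange(0, duration - n_b * isi, period)
    train = np.sort(np.concatenate([onsets + k * isi for k in range(n_b)]))
    src = Population("in", 1, kind="source", trains=[train])
    out = Population("out", 1, kind="lif", params=lif, record_v=True)
    proj = connect("plastic", src, out, "all-to-all", weight=w0, delay=1,
                   plastic=True, rule=rule)
    net = Network([src, out], [proj])
    rec = Simulator(net, snapshot_weights="boundaries").run(duration, seed=seed)
    stf = spikes_to_fire(rec.spike_times("in"), rec.spike_times("out"), onsets, period)
    metrics = {
        "branch": branch,
        "w0": w0,
        "w_max": w_max,
        "spikes_to_fire": stf,
        "initial_spikes_to_fire": stf[0],
        "final_spikes_to_fire": stf[-1],
        "final_weight": float(proj.weights[0]),
        "post_spikes_last_quarter": int(
            np.count_nonzero(rec.spike_times("out") >= 3 * duration // 4)
        ),
    }
    return ExperimentResult("vg_demo", seed, rec, rec.weight_snapshots, metrics)


def run_temporal_experiment(seed: int = 0, pattern: str = "forward", **overrides) -> ExperimentResult:
    """Temporal pattern learning on a tonotopic delay-line network.

    Each frequency channel has neurons A (cochlea source), B1 and B2;
    cross-channel B1->B2 connections are plastic under the voltage-gated
    rule with delays proportional to channel distance, so a frequency sweep
    potentiates exactly the connections whose delay compensates the
    channel lag.  The learned matrix is summarised by its below/above
    diagonal asymmetry: positive for a forward sweep, negative for
    backward, near zero for a forked sweep."""
    cfg = {**load_fixture("temporal"), **overrides}
    lif = _lif_from(cfg.get("lif"))
    n = cfg["n_channels"]
    sweep = stimuli.SweepPattern(
        pattern, n, cfg["inter_channel_dt_ms"], cfg["repeat_gap_ms"], cfg["repeats"],
    )
    trains = stimuli.sweep_spikes(sweep)
    duration = cfg["repeats"] * cfg["repeat_gap_ms"]
    a_pop = Population("A", n, kind="source", trains=trains)
    b1 = Population("B1", n, kind="lif", params=lif)
    b2 = Population("B2", n, kind="lif", params=lif, record_v=True)
    rule = make_rule("vg_stdp", **cfg["vg"])
    radius = cfg["neighbor_radius"]
    pre_x, post_x = np.nonzero(
        (np.abs(np.arange(n)[:, None] - np.arange(n)[None, :]) <= radius)
        & ~np.eye(n, dtype=bool)
    )
    dist = np.abs(pre_x - post_x)
    w_rng = rng_stream(seed, "weights")
    w_init = w_rng.uniform(cfg["w_init_lo"], cfg["w_init_hi"], size=len(pre_x))
    plastic = Projection(
        "plastic", b1, b2, pre_x, post_x, w_init,
        (dist * cfg["inter_channel_dt_ms"]).astype(np.int64),
        plastic=True, rule=rule,
    )
    projs = [
        connect("a_b1", a_pop, b1, "one-to-one", cfg["a_b1_w"], 1),
        connect("a_b2", a_pop, b2, "one-to-one", cfg["a_b2_w"], 1),
        connect("b1_b2_inh", b1, b2, "one-to-one", cfg["b1_b2_inh_w"], 1),
        plastic,
    ]
    net = Network([a_pop, b1, b2], projs)
    rec = Simulator(net).run(duration, seed=seed)
    matrix = plastic.weight_matrix()
    metrics = {
        "pattern": pattern,
        "asymmetry": weight_asymmetry(matrix),
        "weight_matrix": matrix.tolist(),
        "sum_w_final": float(plastic.weights.sum()),
    }
    return ExperimentResult("temporal", seed, rec, rec.weight_snapshots, metrics)


# --------------------------------------------------------------------------
# registry
# --------------------------------------------------------------------------

EXPERIMENTS = {
    "potentiation": run_potentiation_experiment,
    "latency": run_latency_experiment,
    "teacher_stdp": run_teacher_experiment,
    "song": run_song_experiment,
    "bcm_teacher": run_bcm_teacher_experiment,
    "orientation": run_orientation_experiment,
    "vg_demo": run_vg_experiment,
    "temporal": run_temporal_experiment,
}


def run_experiment(name: str, seed: int = 0, **kwargs) -> ExperimentResult:
    if name not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {name!r}; choose from {sorted(EXPERIMENTS)}")
    return EXPERIMENTS[name](seed=seed, **kwargs)
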