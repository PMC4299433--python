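"""Discrete-time (1 ms) simulation kernel.

Current-based leaky integrate-and-fire neurons with exact per-step
exponential integration, integer-millisecond synaptic delays reintroduced
at the post-synaptic end through a per-neuron input ring buffer, and
deterministic event ordering within a step:

    stimulus spikes -> spike delivery -> neuron update -> plasticity bookkeeping

A spike delivered into slot ``t`` is consumed by the neuron update of step
``t``, so an input arriving at ``t`` can influence the spike emitted at
``t``.  All randomness is injected through pre-generated source spike
trains; the kernel itself is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from . import framework

DT_MS = 1.0

__all__ = [
    "LIFParams",
    "NeuronState",
    "SynapticRow",
    "InputRingBuffer",
    "Population",
    "Projection",
    "Network",
    "RecordingSet",
    "Simulator",
    "SimulationError",
    "ValidationError",
    "step_neuron",
    "deliver_spike",
    "run",
]


class SimulationError(RuntimeError):
    """Raised when the kernel reaches an invalid numerical state."""


class ValidationError(ValueError):
    """Raised when a network description is inconsistent."""


# --------------------------------------------------------------------------
# neuron model
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LIFParams:
    """Parameters of a current-based LIF neuron (mV / ms / nA / MOhm)."""

    v_rest: float = -65.0
    v_reset: float = -65.0
    v_thresh: float = -50.0
    tau_m: float = 20.0
    tau_syn: float = 5.0
    r_m: float = 1.0
    t_refrac: float = 2.0
    i_offset: float = 0.0

    def __post_init__(self) -> None:
        if not (self.tau_m > 0 and self.tau_syn > 0):
            raise ValidationError("tau_m and tau_syn must be positive")
        if not self.v_thresh > self.v_reset:
            raise ValidationError("v_thresh must exceed v_reset")
        if self.t_refrac < 0:
            raise ValidationError("t_refrac must be >= 0")

    def step_coefficients(self, dt: float = DT_MS) -> tuple[float, float, float]:
        """Exact decay factors (a, b, c) for one step of length ``dt``.

        ``a`` decays the membrane deviation, ``b`` the synaptic current and
        ``c`` maps the start-of-step current onto the membrane (the exact
        convolution of an exponential current with the membrane filter).
        """
        a = math.exp(-dt / self.tau_m)
        b = math.exp(-dt / self.tau_syn)
        if abs(self.tau_syn - self.tau_m) < 1e-9 * self.tau_m:
            c = (dt / self.tau_m) * a
        else:
            c = (self.tau_syn / (self.tau_syn - self.tau_m)) * (b - a)
        return a, b, c


@dataclass
class NeuronState:
    """Scalar LIF state (vectorised internally as :class:`_LIFStateVec`)."""

    v: float
    i_syn: float = 0.0
    refrac_remaining: float = 0.0
    last_spike_time: Optional[float] = None


def step_neuron(
    state: NeuronState,
    params: LIFParams,
    input_weight: float = 0.0,
    t: float = 0.0,
) -> tuple[NeuronState, bool]:
    """Advance one neuron by 1 ms; ``input_weight`` is the accumulated
    synaptic weight (nA) landing in this millisecond's buffer slot.

    Returns the new state and whether a spike was emitted at the end of
    the step.  Raises :class:`SimulationError` on non-finite values.
    """
    a, b, c = params.step_coefficients()
    i0 = state.i_syn + input_weight
    v_drive = params.v_rest + params.r_m * params.i_offset
    v_new = v_drive + (state.v - v_drive) * a + params.r_m * i0 * c
    i_new = i0 * b
    refrac = state.refrac_remaining
    spiked = False
    last = state.last_spike_time
    if refrac > 0:
        v_new = params.v_reset
        refrac = max(0.0, refrac - DT_MS)
    elif v_new >= params.v_thresh:
        spiked = True
        v_new = params.v_reset
        refrac = params.t_refrac
        last = t
    if not (math.isfinite(v_new) and math.isfinite(i_new)):
        raise SimulationError(f"non-finite neuron state at t={t} ms")
    return NeuronState(v_new, i_new, refrac, last), spiked


class _LIFStateVec:
    """Vectorised LIF state for one population."""

    def __init__(self, n: int, params: LIFParams):
        self.params = params
        self.v = np.full(n, params.v_rest, dtype=np.float64)
        self.i_syn = np.zeros((n, 2), dtype=np.float64)  # exc / inh lanes
        self.refrac = np.zeros(n, dtype=np.float64)
        self.last_spike = np.full(n, -1.0, dtype=np.float64)
        self._coeffs = params.step_coefficients()

    def step(self, inp: np.ndarray, t: float) -> np.ndarray:
        """One 1 ms update. ``inp`` is (n, 2) accumulated weights for this
        millisecond.  Returns indices of neurons spiking at step end."""
        p = self.params
        a, b, c = self._coeffs
        i0 = self.i_syn + inp
        total = i0.sum(axis=1)
        v_drive = p.v_rest + p.r_m * p.i_offset
        self.v = v_drive + (self.v - v_drive) * a + p.r_m * total * c
        self.i_syn = i0 * b
        in_refrac = self.refrac > 0
        if in_refrac.any():
            self.v[in_refrac] = p.v_reset
            self.refrac[in_refrac] -= DT_MS
            np.clip(self.refrac, 0.0, None, out=self.refrac)
        spiked = np.flatnonzero(~in_refrac & (self.v >= p.v_thresh))
        if spiked.size:
            self.v[spiked] = p.v_reset
            self.refrac[spiked] = p.t_refrac
            self.last_spike[spiked] = t
        if not np.isfinite(self.v).all():
            bad = int(np.flatnonzero(~np.isfinite(self.v))[0])
            raise SimulationError(f"non-finite membrane potential, neuron {bad} at t={t} ms")
        return spiked


# --------------------------------------------------------------------------
# connectivity
# --------------------------------------------------------------------------


@dataclass
class SynapticRow:
    """All synapses sharing one pre-synaptic neuron (a view into the
    projection's flat arrays; mutating ``weights`` mutates the projection)."""

    pre_id: int
    post_ids: np.ndarray
    weights: np.ndarray
    delays: np.ndarray
    plastic: bool = False


class Projection:
    """Connections from one population to another, stored row-major
    (CSR over pre-synaptic neurons, entries sorted by post id)."""

    def __init__(
        self,
        name: str,
        pre: "Population",
        post: "Population",
        pre_ids: np.ndarray,
        post_ids: np.ndarray,
        weights: np.ndarray,
        delays: np.ndarray,
        plastic: bool = False,
        rule=None,
    ):
        order = np.lexsort((post_ids, pre_ids))
        pre_ids = np.asarray(pre_ids, dtype=np.int64)[order]
        self.name = name
        self.pre = pre
        self.post = post
        self.post_ids = np.asarray(post_ids, dtype=np.int64)[order]
        self.weights = np.asarray(weights, dtype=np.float64)[order].copy()
        self.delays = np.asarray(delays, dtype=np.int64)[order]
        self.plastic = bool(plastic)
        self.rule = rule
        if np.any(self.delays < 1):
            raise ValidationError(f"projection {name}: delays must be >= 1 ms")
        if np.any(self.post_ids < 0) or np.any(self.post_ids >= post.size):
            raise ValidationError(f"projection {name}: post id out of range")
        if np.any(pre_ids < 0) or np.any(pre_ids >= pre.size):
            raise ValidationError(f"projection {name}: pre id out of range")
        # CSR index over pre neurons
        self.indptr = np.zeros(pre.size + 1, dtype=np.int64)
        np.add.at(self.indptr, pre_ids + 1, 1)
        np.cumsum(self.indptr, out=self.indptr)
        self.pre_of_entry = pre_ids
        if plastic and rule is None:
            raise ValidationError(f"projection {name}: plastic but no rule attached")

    @property
    def n_entries(self) -> int:
        return len(self.post_ids)

    def row(self, pre_id: int) -> SynapticRow:
        lo, hi = self.indptr[pre_id], self.indptr[pre_id + 1]
        return SynapticRow(
            pre_id,
            self.post_ids[lo:hi],
            self.weights[lo:hi],
            self.delays[lo:hi],
            self.plastic,
        )

    def weight_matrix(self) -> np.ndarray:
        """Dense (n_pre, n_post) matrix; absent synapses are NaN-free zeros."""
        m = np.zeros((self.pre.size, self.post.size))
        m[self.pre_of_entry, self.post_ids] = self.weights
        return m

    @property
    def max_delay(self) -> int:
        return int(self.delays.max()) if self.n_entries else 1


def _pair_arrays(kind: str, n_pre: int, n_post: int, rng=None, p: float = 1.0):
    if kind == "all-to-all":
        pre = np.repeat(np.arange(n_pre), n_post)
        post = np.tile(np.arange(n_post), n_pre)
    elif kind == "one-to-one":
        if n_pre != n_post:
            raise ValidationError("one-to-one requires equal population sizes")
        pre = np.arange(n_pre)
        post = np.arange(n_post)
    elif kind == "bernoulli":
        if rng is None:
            raise ValidationError("bernoulli connectivity needs an rng")
        mask = rng.random((n_pre, n_post)) < p
        pre, post = np.nonzero(mask)
    else:
        raise ValidationError(f"unknown connectivity kind: {kind!r}")
    return pre, post


def connect(
    name: str,
    pre: "Population",
    post: "Population",
    kind: str,
    weight,
    delay,
    plastic: bool = False,
    rule=None,
    p: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> Projection:
    """Build a projection.  ``weight``/``delay`` may be scalars, arrays of
    the right length, or callables ``f(pre_ids, post_ids) -> array``."""
    pre_ids, post_ids = _pair_arrays(kind, pre.size, post.size, rng=rng, p=p)
    n = len(pre_ids)

    def expand(x, dtype):
        if callable(x):
            return np.asarray(x(pre_ids, post_ids), dtype=dtype)
        arr = np.asarray(x, dtype=dtype)
        return np.broadcast_to(arr, (n,)).copy() if arr.ndim == 0 else arr

    return Projection(
        name, pre, post, pre_ids, post_ids,
        expand(weight, np.float64), expand(delay, np.int64),
        plastic=plastic, rule=rule,
    )


# --------------------------------------------------------------------------
# input ring buffer
# --------------------------------------------------------------------------


class InputRingBuffer:
    """Per-neuron circular accumulator of per-millisecond synaptic input,
    one lane per synapse type (0 excitatory, 1 inhibitory).  The slot
    consumed at time t is zeroed after use."""

    def __init__(self, n_neurons: int, span: int):
        if span < 2:
            raise ValidationError("ring buffer span must cover max delay + 1")
        self.span = int(span)
        self.buf = np.zeros((self.span, n_neurons, 2), dtype=np.float64)

    def add(self, t_arrival: np.ndarray, post_ids: np.ndarray, weights: np.ndarray) -> None:
        lanes = (np.asarray(weights) < 0).astype(np.int64)
        np.add.at(
            self.buf,
            (np.asarray(t_arrival, dtype=np.int64) % self.span, post_ids, lanes),
            weights,
        )

    def take(self, t: int) -> np.ndarray:
        slot = int(t) % self.span
        out = self.buf[slot].copy()
        self.buf[slot] = 0.0
        return out


def deliver_spike(row: SynapticRow, buffers: InputRingBuffer, t: int) -> None:
    """Deliver one pre spike at time ``t`` through ``row``: each entry's
    weight accumulates into the target's buffer slot ``t + delay``."""
    if len(row.post_ids) == 0:
        return
    buffers.add(t + row.delays, row.post_ids, row.weights)


# --------------------------------------------------------------------------
# populations and network
# --------------------------------------------------------------------------


class SpikeTrainSet:
    """Per-source spike trains indexed by millisecond for fast replay."""

    def __init__(self, trains: Sequence[np.ndarray], duration: int):
        self.trains = [np.asarray(tr, dtype=np.int64) for tr in trains]
        times = []
        ids = []
        for i, tr in enumerate(self.trains):
            if len(tr):
                if np.any(tr < 0):
                    raise ValidationError("negative spike time in source train")
                times.append(tr)
                ids.append(np.full(len(tr), i, dtype=np.int64))
        if times:
            t = np.concatenate(times)
            n = np.concatenate(ids)
            keep = t < duration
            t, n = t[keep], n[keep]
            order = np.argsort(t, kind="stable")
            self._t, self._ids = t[order], n[order]
        else:
            self._t = np.empty(0, dtype=np.int64)
            self._ids = np.empty(0, dtype=np.int64)
        self.indptr = np.searchsorted(self._t, np.arange(duration + 1))

    def at(self, t: int) -> np.ndarray:
        lo, hi = self.indptr[t], self.indptr[t + 1]
        return self._ids[lo:hi]


class Population:
    """A named group of neurons: either LIF cells or spike sources.

    Spike sources carry a ``stimulus`` callable ``(rng, duration) -> list of
    per-neuron spike-time arrays`` (or fixed trains) materialised at run
    start from the population's named random sub-stream."""

    def __init__(
        self,
        name: str,
        size: int,
        kind: str = "lif",
        params: Optional[LIFParams] = None,
        stimulus: Optional[Callable] = None,
        trains: Optional[Sequence[np.ndarray]] = None,
        record_v: bool = False,
    ):
        if size < 1:
            raise ValidationError(f"population {name}: size must be >= 1")
        if kind not in ("lif", "source"):
            raise ValidationError(f"population {name}: unknown kind {kind!r}")
        self.name = name
        self.size = int(size)
        self.kind = kind
        self.params = params or (LIFParams() if kind == "lif" else None)
        self.stimulus = stimulus
        self.trains = trains
        self.record_v = record_v


class Network:
    def __init__(self, populations: Sequence[Population], projections: Sequence[Projection]):
        self.populations = {p.name: p for p in populations}
        if len(self.populations) != len(populations):
            raise ValidationError("duplicate population names")
        self.projections = list(projections)
        self.validate()

    def validate(self) -> None:
        names = {id(p) for p in self.populations.values()}
        seen = set()
        for proj in self.projections:
            if id(proj.pre) not in names or id(proj.post) not in names:
                raise ValidationError(
                    f"projection {proj.name} references a population outside the network"
                )
            if proj.post.kind != "lif":
                raise ValidationError(f"projection {proj.name}: target must be a lif population")
            if proj.name in seen:
                raise ValidationError(f"duplicate projection name {proj.name}")
            seen.add(proj.name)


# --------------------------------------------------------------------------
# recordings
# --------------------------------------------------------------------------


@dataclass
class RecordingSet:
    """Simulation outputs: spike times per population, optional membrane
    traces, weight snapshots taken at plasticity boundaries, and the
    write-back ledgers of plastic projections."""

    duration: int
    spikes: dict = field(default_factory=dict)        # pop -> (times, ids) int arrays
    v_traces: dict = field(default_factory=dict)      # pop -> (duration, n) float
    weight_snapshots: dict = field(default_factory=dict)  # proj -> list[(t, flat weights)]
    ledgers: dict = field(default_factory=dict)       # proj -> framework.WritebackLedger

    def spike_times(self, pop: str, neuron: Optional[int] = None) -> np.ndarray:
        t, ids = self.spikes[pop]
        return t if neuron is None else t[ids == neuron]

    def rate(self, pop: str, neuron: int, t0: float = 0.0, t1: Optional[float] = None) -> float:
        """Mean firing rate in Hz over [t0, t1)."""
        t1 = self.duration if t1 is None else t1
        times = self.spike_times(pop, neuron)
        n = int(np.count_nonzero((times >= t0) & (times < t1)))
        return 1000.0 * n / (t1 - t0) if t1 > t0 else 0.0


# --------------------------------------------------------------------------
# simulator
# --------------------------------------------------------------------------


class Simulator:
    """Runs a :class:`Network` for a fixed duration with batched plasticity.

    Plasticity passes execute at each window boundary on the previous
    window's double-buffered spike histories; a final pass covers a
    trailing partial window so that every window started within
    ``[0, duration)`` is written back exactly once (batched accounting).
    """

    def __init__(self, network: Network, window_ms: int = 128, bin_ms: int = 2,
                 snapshot_weights: str = "edges"):
        if window_ms % bin_ms != 0:
            raise ValidationError("window_ms must be a multiple of bin_ms")
        if snapshot_weights not in ("edges", "boundaries", "none"):
            raise ValidationError("snapshot_weights must be edges|boundaries|none")
        self.network = network
        self.window_ms = int(window_ms)
        self.bin_ms = int(bin_ms)
        self.snapshot_weights = snapshot_weights

    # -- internals ---------------------------------------------------------

    def _deliver_from(self, proj: Projection, ids: np.ndarray, t: int,
                      ring: InputRingBuffer) -> None:
        lo = proj.indptr[ids]
        hi = proj.indptr[ids + 1]
        reps = hi - lo
        total = int(reps.sum())
        if total == 0:
            return
        offs = np.repeat(np.cumsum(reps) - reps, reps)
        eidx = np.arange(total) - offs + np.repeat(lo, reps)
        ring.add(t + proj.delays[eidx], proj.post_ids[eidx], proj.weights[eidx])

    def run(self, duration: int, seed: int = 0) -> RecordingSet:
        net = self.network
        duration = int(duration)
        rec = RecordingSet(duration=duration)
        if duration < 0:
            raise ValidationError("duration must be >= 0")

        # materialise source spike trains from per-population sub-streams
        trains: dict[str, SpikeTrainSet] = {}
        for pop in net.populations.values():
            if pop.kind != "source":
                continue
            if pop.trains is not None:
                raw = pop.trains
            elif pop.stimulus is not None:
                raw = pop.stimulus(rng_stream(seed, f"stimulus:{pop.name}"), duration)
            else:
                raw = [np.empty(0, dtype=np.int64) for _ in range(pop.size)]
            if len(raw) != pop.size:
                raise ValidationError(f"population {pop.name}: got {len(raw)} trains")
            trains[pop.name] = SpikeTrainSet(raw, duration)

        # per-population machinery
        states = {
            p.name: _LIFStateVec(p.size, p.params)
            for p in net.populations.values() if p.kind == "lif"
        }
        max_delay = max((pr.max_delay for pr in net.projections), default=1)
        rings = {
            p.name: InputRingBuffer(p.size, max_delay + 2)
            for p in net.populations.values() if p.kind == "lif"
        }
        outgoing: dict[str, list[Projection]] = {n: [] for n in net.populations}
        for proj in net.projections:
            outgoing[proj.pre.name].append(proj)

        # plasticity bookkeeping
        plastic = [p for p in net.projections if p.plastic]
        pstates = {
            p.name: framework.ProjectionPlasticState(p, self.window_ms, self.bin_ms)
            for p in plastic
        }
        incoming_plastic: dict[str, list] = {n: [] for n in net.populations}
        for p in plastic:
            incoming_plastic[p.post.name].append(pstates[p.name])
            rec.ledgers[p.name] = pstates[p.name].ledger
            if self.snapshot_weights != "none":
                rec.weight_snapshots[p.name] = [(0, p.weights.copy())]

        spike_times_acc: dict[str, list] = {n: [] for n in net.populations}
        spike_ids_acc: dict[str, list] = {n: [] for n in net.populations}
        for pop in net.populations.values():
            if pop.record_v and pop.kind == "lif":
                rec.v_traces[pop.name] = np.empty((duration, pop.size))

        def emit(pop_name: str, ids: np.ndarray, t: int) -> None:
            if ids.size == 0:
                return
            spike_times_acc[pop_name].append(np.full(ids.size, t, dtype=np.int64))
            spike_ids_acc[pop_name].append(np.asarray(ids, dtype=np.int64))
            for proj in outgoing[pop_name]:
                self._deliver_from(proj, ids, t, rings[proj.post.name])
                if proj.plastic:
                    pstates[proj.name].record_pre(ids, t)
            for ps in incoming_plastic[pop_name]:
                ps.record_post(ids, t)

        def boundary(t_boundary: int) -> None:
            for proj in plastic:
                ps = pstates[proj.name]
                ps.run_pass(t_boundary)
                if self.snapshot_weights == "boundaries":
                    rec.weight_snapshots[proj.name].append((t_boundary, proj.weights.copy()))

        for t in range(duration):
            # 1. stimulus spikes
            for pop_name, ts in trains.items():
                emit(pop_name, ts.at(t), t)
            # 2-3. delivery already buffered; neuron update
            for pop_name, state in states.items():
                inp = rings[pop_name].take(t)
                spiked = state.step(inp, t)
                if pop_name in rec.v_traces:
                    rec.v_traces[pop_name][t] = state.v
                emit(pop_name, spiked, t)
            # voltage gate bitmaps for rules that need them
            for pop_name, state in states.items():
                for ps in incoming_plastic[pop_name]:
                    if ps.needs_voltage:
                        ps.record_voltage(state.v, t)
            # 4. plasticity bookkeeping at window boundaries
            if (t + 1) % self.window_ms == 0:
                boundary(t + 1)

        if duration % self.window_ms != 0:
            boundary(duration)  # trailing partial window
        if self.snapshot_weights != "none":
            for proj in plastic:
                snaps = rec.weight_snapshots[proj.name]
                if not snaps or snaps[-1][0] != duration:
                    snaps.append((duration, proj.weights.copy()))

        for name in net.populations:
            if spike_times_acc[name]:
                rec.spikes[name] = (
                    np.concatenate(spike_times_acc[name]),
                    np.concatenate(spike_ids_acc[name]),
                )
            else:
                rec.spikes[name] = (
                    np.empty(0, dtype=np.int64),
                    np.empty(0, dtype=np.int64),
                )
        return rec


def run(network: Network, duration: int, seed: int = 0, window_ms: int = 128,
        bin_ms: int = 2, **kw) -> RecordingSet:
    """Convenience wrapper: build a :class:`Simulator` and run it."""
    return Simulator(network, window_ms=window_ms, bin_ms=bin_ms, **kw).run(duration, seed)


def rng_stream(seed: int, name: str) -> np.random.Generator:
    """Named deterministic sub-stream of a global seed."""
    import zlib

    return np.random.default_rng([int(seed) & 0xFFFFFFFF, zlib.crc32(name.encode())])
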