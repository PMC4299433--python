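"""Weight-update rules operating on completed spike windows.

Three rules share the batched row-walking pass of :mod:`spikewin.framework`:

* trace-based STDP -- all-to-all pair sums of a double-exponential kernel,
  computed from exponentially decaying pre/post traces that carry over
  between windows; pre spike times are shifted by the synaptic delay before
  any comparison with post spikes (the delay is reintroduced at the
  post-synaptic end).
* BCM -- rate-based Hebbian rule with a sliding modification threshold
  (exponential moving average of the post rate) applied once per window.
* voltage-gated bistable STDP -- pre-spike-triggered jumps gated by the
  post membrane potential and a calcium trace of post spikes, with a drift
  toward one of two stable weight values between events.

Weight updates are computed in double precision and clipped to the rule's
``[w_min, w_max]`` at the end of each pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .framework import SpikeWindow, WindowView, ProjectionPlasticState, bin_centers

__all__ = [
    "STDPParams", "TraceState", "stdp_F", "update_trace", "STDPRule",
    "stdp_update_row",
    "BCMParams", "BCMState", "bcm_dw", "update_theta", "BCMRule",
    "VGParams", "CalciumTrace", "calcium_step", "VGRule", "vg_update_row",
    "make_rule",
]


# ==========================================================================
# trace-based STDP
# ==========================================================================


@dataclass(frozen=True)
class STDPParams:
    a_plus: float = 0.1
    a_minus: float = 0.1
    tau_plus: float = 20.0
    tau_minus: float = 20.0
    w_min: float = 0.0
    w_max: float = 1.0

    def __post_init__(self):
        if self.a_plus < 0 or self.a_minus < 0:
            raise ValueError("A_plus and A_minus must be >= 0")
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("tau_plus and tau_minus must be > 0")
        if self.w_min > self.w_max:
            raise ValueError("w_min must not exceed w_max")


def stdp_F(delta_t, params: STDPParams):
    """Pairwise weight change for a pre-post time difference
    ``delta_t = t_pre - t_post`` (delay already applied to the pre time):
    potentiation ``A+ * exp(dt/tau+)`` for dt < 0, depression
    ``-A- * exp(-dt/tau-)`` for dt >= 0."""
    dt = np.asarray(delta_t, dtype=np.float64)
    out = np.where(
        dt < 0,
        params.a_plus * np.exp(np.minimum(dt, 0.0) / params.tau_plus),
        -params.a_minus * np.exp(-np.maximum(dt, 0.0) / params.tau_minus),
    )
    return float(out) if np.isscalar(delta_t) else out


@dataclass
class TraceState:
    """Exponentially decaying spike trace: ``dx/dt = -x/tau`` plus a jump
    of ``A`` at every spike.  Carries over across plasticity windows."""

    x: float = 0.0
    tau: float = 20.0
    a: float = 1.0
    last_update_t: float = 0.0


def update_trace(trace: TraceState, spike_times: Sequence[float], now: float) -> TraceState:
    """Exact trace update: decay between spikes, jump by ``A`` per spike,
    evaluated at ``now``.  Spike times must be ordered and within
    ``[trace.last_update_t, now]``."""
    times = np.asarray(spike_times, dtype=np.float64)
    if times.size and np.any(np.diff(times) < 0):
        raise ValueError("spike times must be chronologically ordered")
    if times.size and (times[0] < trace.last_update_t or times[-1] > now):
        raise ValueError("spike times must lie within (last_update_t, now]")
    x, t = trace.x, trace.last_update_t
    for ts in times:
        x = x * math.exp(-(ts - t) / trace.tau) + trace.a
        t = ts
    x = x * math.exp(-(now - t) / trace.tau)
    return TraceState(x, trace.tau, trace.a, now)


def _stdp_window_core(
    t0: float,
    t1: float,
    arr_eidx: np.ndarray,
    arr_t: np.ndarray,
    post_jidx: np.ndarray,
    post_t: np.ndarray,
    post_of_entry: np.ndarray,
    x_pre: np.ndarray,
    x_post: np.ndarray,
    p: STDPParams,
) -> np.ndarray:
    """All-to-all trace update over one window.

    ``arr_*``: delay-shifted pre arrival events (entry index, time);
    ``post_*``: post spike events (post index, time).  ``x_pre`` is the
    per-entry trace of arrivals (amplitude A+), ``x_post`` the per-post
    trace (amplitude A-), both valid at ``t0``; they are updated in place
    to ``t1``.  Returns the accumulated weight change per entry.

    Tie rule: a pre arrival coincident with a post spike pairs through the
    depression branch only (F(0) = -A-).
    """
    dw = np.zeros(len(post_of_entry))
    span = t1 - t0
    # carried traces x pairs across the window start
    if post_t.size:
        s_pot = np.zeros(x_post.shape)
        np.add.at(s_pot, post_jidx, np.exp(-(post_t - t0) / p.tau_plus))
        dw += x_pre * s_pot[post_of_entry]
    if arr_t.size:
        dep_carry = x_post[post_of_entry[arr_eidx]] * np.exp(-(arr_t - t0) / p.tau_minus)
        np.add.at(dw, arr_eidx, -dep_carry)
    # within-window pairs
    if arr_t.size and post_t.size:
        same = post_of_entry[arr_eidx][:, None] == post_jidx[None, :]
        dtm = post_t[None, :] - arr_t[:, None]  # t_post - t_arrival
        pot = p.a_plus * np.exp(-np.maximum(dtm, 0.0) / p.tau_plus)
        dep = p.a_minus * np.exp(np.minimum(dtm, 0.0) / p.tau_minus)
        contrib = np.where(dtm > 0, pot, -dep) * same
        np.add.at(dw, arr_eidx, contrib.sum(axis=1))
    # advance traces to t1
    x_pre *= math.exp(-span / p.tau_plus)
    if arr_t.size:
        np.add.at(x_pre, arr_eidx, p.a_plus * np.exp(-(t1 - arr_t) / p.tau_plus))
    x_post *= math.exp(-span / p.tau_minus)
    if post_t.size:
        np.add.at(x_post, post_jidx, p.a_minus * np.exp(-(t1 - post_t) / p.tau_minus))
    return dw


class STDPRule:
    """Trace-based all-to-all STDP (``rule.name = stdp_trace``)."""

    name = "stdp_trace"
    needs_voltage = False

    def __init__(self, params: STDPParams):
        self.params = params

    @property
    def w_min(self) -> float:
        return self.params.w_min

    @property
    def w_max(self) -> float:
        return self.params.w_max

    def init_state(self, proj) -> dict:
        return {
            "x_pre": np.zeros(proj.n_entries),
            "x_post": np.zeros(proj.post.size),
        }

    def process_window(self, proj, state: ProjectionPlasticState, view: WindowView) -> np.ndarray:
        eidx, at = state.take_arrivals(view)
        jidx, pt = view.post_events()
        dw = _stdp_window_core(
            view.t0, view.t1, eidx, at, jidx, pt,
            proj.post_ids,
            state.rule_state["x_pre"], state.rule_state["x_post"],
            self.params,
        )
        return proj.weights + dw


def stdp_update_row(
    row,
    pre_window: SpikeWindow,
    post_windows: dict,
    pre_traces: np.ndarray,
    post_traces: dict,
    params: STDPParams,
    t1: Optional[float] = None,
) -> np.ndarray:
    """Row-level STDP update (contract form of the batched pass).

    ``pre_window`` holds the row's pre spikes; ``post_windows`` maps post id
    to its spike window; ``pre_traces`` is the per-entry arrival-trace array
    and ``post_traces`` maps post id to its trace value, both mutated to the
    window end.  Returns the row's updated, clipped weights.
    """
    t0 = pre_window.phase_start
    t1 = t0 + pre_window.window_span if t1 is None else t1
    centers = bin_centers(t0, pre_window.n_bins, pre_window.bin_ms)
    n = len(row.post_ids)
    arr_e, arr_t = [], []
    for e in range(n):
        times = centers[pre_window.bits] + row.delays[e]
        times = times[times < t1]  # contract form: callers keep arrivals in-window
        arr_e.extend([e] * len(times))
        arr_t.extend(times)
    post_ids = np.asarray(row.post_ids)
    uniq = list(dict.fromkeys(post_ids.tolist()))
    jmap = {j: k for k, j in enumerate(uniq)}
    pj, pt = [], []
    for j in uniq:
        w = post_windows[j]
        times = bin_centers(w.phase_start, w.n_bins, w.bin_ms)[w.bits]
        pj.extend([jmap[j]] * len(times))
        pt.extend(times)
    x_post = np.array([post_traces[j] for j in uniq], dtype=np.float64)
    order = np.argsort(np.asarray(arr_t, dtype=np.float64), kind="stable")
    dw = _stdp_window_core(
        t0, t1,
        np.asarray(arr_e, dtype=np.int64)[order],
        np.asarray(arr_t, dtype=np.float64)[order],
        np.asarray(pj, dtype=np.int64),
        np.asarray(pt, dtype=np.float64),
        np.asarray([jmap[j] for j in post_ids], dtype=np.int64),
        pre_traces, x_post, params,
    )
    for j in uniq:
        post_traces[j] = float(x_post[jmap[j]])
    row.weights[:] = np.clip(row.weights + dw, params.w_min, params.w_max)
    return row.weights


# ==========================================================================
# BCM
# ==========================================================================


@dataclass(frozen=True)
class BCMParams:
    delta: float = 1e-4        # learning rate
    epsilon: float = 0.0       # weight decay
    theta_ema: float = 0.5     # EMA coefficient for the threshold, 0 = frozen
    rate_lp: float = 1.0       # single-pole low-pass for the post rate
    w_min: float = 0.0
    w_max: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.theta_ema <= 1.0:
            raise ValueError("theta_ema must be in [0, 1]")
        if not 0.0 < self.rate_lp <= 1.0:
            raise ValueError("rate_lp must be in (0, 1]")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.w_min > self.w_max:
            raise ValueError("w_min must not exceed w_max")


@dataclass
class BCMState:
    r_pre: np.ndarray
    r_post: np.ndarray
    theta: np.ndarray
    initialized: bool = False


def bcm_dw(r_pre, r_post, theta, w, params: BCMParams, dt_s: float = 0.128):
    """Per-window weight change: ``[r_post (r_post - theta) r_pre] delta -
    epsilon w`` integrated over one window of ``dt_s`` seconds."""
    hebb = r_post * (r_post - theta) * r_pre * params.delta
    return (hebb - params.epsilon * np.asarray(w)) * dt_s


def update_theta(theta, r_post_window, theta_ema: float):
    """Sliding modification threshold: exponential moving average of the
    post rate, updated once per completed window."""
    return (1.0 - theta_ema) * np.asarray(theta, dtype=np.float64) + theta_ema * np.asarray(
        r_post_window, dtype=np.float64
    )


class BCMRule:
    """Rate-based BCM with sliding threshold (``rule.name = bcm``).

    Rates are measured per window: the pre rate from the pre spike bitmap,
    the post rate from the exact per-window spike counter, optionally
    low-pass filtered.  The threshold starts at the first window's measured
    post rate and thereafter follows the configured EMA of the raw window
    rate; the Hebbian term uses the filtered rate and the pre-update
    threshold.
    """

    name = "bcm"
    needs_voltage = False

    def __init__(self, params: BCMParams):
        self.params = params

    @property
    def w_min(self) -> float:
        return self.params.w_min

    @property
    def w_max(self) -> float:
        return self.params.w_max

    def init_state(self, proj) -> BCMState:
        return BCMState(
            r_pre=np.zeros(proj.pre.size),
            r_post=np.zeros(proj.post.size),
            theta=np.zeros(proj.post.size),
        )

    def process_window(self, proj, state: ProjectionPlasticState, view: WindowView) -> np.ndarray:
        st: BCMState = state.rule_state
        p = self.params
        span = view.span
        if span <= 0:
            return proj.weights.copy()
        r_pre_win = view.pre_bits.sum(axis=1) * 1000.0 / span
        r_post_win = view.post_counts * 1000.0 / span
        if not st.initialized:
            st.theta = r_post_win.astype(np.float64)
            st.r_post = r_post_win.astype(np.float64)
            st.initialized = True
        else:
            st.r_post = (1.0 - p.rate_lp) * st.r_post + p.rate_lp * r_post_win
        st.r_pre = r_pre_win.astype(np.float64)
        dw = bcm_dw(
            st.r_pre[proj.pre_of_entry],
            st.r_post[proj.post_ids],
            st.theta[proj.post_ids],
            proj.weights,
            p,
            dt_s=span / 1000.0,
        )
        st.theta = update_theta(st.theta, r_post_win, p.theta_ema)
        return proj.weights + dw


# ==========================================================================
# voltage-gated bistable STDP
# ==========================================================================


@dataclass(frozen=True)
class VGParams:
    j_c: float = 1.0
    tau_c: float = 60.0
    theta_v: float = -55.0
    theta_h_down: float = 0.0
    theta_h_up: float = math.inf
    theta_l_down: float = 0.0
    theta_l_up: float = math.inf
    a: float = 0.1
    b: float = 0.1
    alpha: float = 0.0          # up-drift per ms
    beta: float = 0.0           # down-drift per ms
    theta_w: float = 0.5
    w_min: float = 0.0
    w_max: float = 1.0

    def __post_init__(self):
        if self.theta_h_down > self.theta_h_up or self.theta_l_down > self.theta_l_up:
            raise ValueError("calcium intervals must satisfy down <= up")
        if min(self.a, self.b, self.alpha, self.beta) < 0:
            raise ValueError("a, b, alpha, beta must be >= 0")
        if not self.w_min <= self.theta_w <= self.w_max:
            raise ValueError("theta_w must lie within [w_min, w_max]")
        if self.tau_c <= 0:
            raise ValueError("tau_c must be > 0")


@dataclass
class CalciumTrace:
    """Calcium concentration trace of post spikes: jump ``J_C`` per spike,
    exponential decay with ``tau_C``."""

    c: float = 0.0
    last_update_t: float = 0.0


def calcium_step(
    ct: CalciumTrace, post_spike_times: Sequence[float], now: float, params: VGParams
) -> CalciumTrace:
    """Exact calcium update to ``now``; k coincident spikes add ``k * J_C``."""
    times = np.asarray(post_spike_times, dtype=np.float64)
    if times.size and np.any(np.diff(times) < 0):
        raise ValueError("spike times must be chronologically ordered")
    c, t = ct.c, ct.last_update_t
    for ts in times:
        c = c * math.exp(-(ts - t) / params.tau_c) + params.j_c
        t = ts
    c = c * math.exp(-(now - t) / params.tau_c)
    return CalciumTrace(c, now)


def _vg_jump(v_gate: np.ndarray, c: np.ndarray, p: VGParams) -> np.ndarray:
    """Weight jump at pre arrival: +a if the voltage gate is open and the
    calcium is in the potentiation interval, -b if closed and in the
    depression interval, else 0."""
    pot = v_gate & (c >= p.theta_h_down) & (c < p.theta_h_up)
    dep = ~v_gate & (c >= p.theta_l_down) & (c < p.theta_l_up)
    return np.where(pot, p.a, 0.0) - np.where(dep, p.b, 0.0)


def _vg_drift(w_start: np.ndarray, span: float, p: VGParams) -> np.ndarray:
    """Bistable relaxation over a window, branch chosen from the
    window-start weight: up-drift alpha above theta_w, down-drift beta at or
    below it."""
    return np.where(w_start > p.theta_w, p.alpha * span, -p.beta * span)


class VGRule:
    """Voltage-gated bistable STDP (``rule.name = vg_stdp``)."""

    name = "vg_stdp"
    needs_voltage = True

    def __init__(self, params: VGParams):
        self.params = params

    @property
    def w_min(self) -> float:
        return self.params.w_min

    @property
    def w_max(self) -> float:
        return self.params.w_max

    @property
    def theta_v(self) -> float:
        return self.params.theta_v

    def init_state(self, proj) -> dict:
        return {"calcium": np.zeros(proj.post.size)}

    def process_window(self, proj, state: ProjectionPlasticState, view: WindowView) -> np.ndarray:
        p = self.params
        c0 = state.rule_state["calcium"]
        eidx, at = state.take_arrivals(view)
        jidx, pt = view.post_events()
        dw = np.zeros(proj.n_entries)
        if at.size:
            j_of_arr = proj.post_ids[eidx]
            c_at = c0[j_of_arr] * np.exp(-(at - view.t0) / p.tau_c)
            if pt.size:
                same = j_of_arr[:, None] == jidx[None, :]
                dtp = at[:, None] - pt[None, :]
                contrib = p.j_c * np.exp(-np.maximum(dtp, 0.0) / p.tau_c)
                c_at = c_at + (contrib * (same & (dtp >= 0))).sum(axis=1)
            gate = view.voltage_at(j_of_arr, at)
            np.add.at(dw, eidx, _vg_jump(gate, c_at, p))
        dw += _vg_drift(proj.weights, view.span, p)
        # calcium to t1
        c1 = c0 * math.exp(-view.span / p.tau_c)
        if pt.size:
            np.add.at(c1, jidx, p.j_c * np.exp(-(view.t1 - pt) / p.tau_c))
        state.rule_state["calcium"] = c1
        return proj.weights + dw


def vg_update_row(
    row,
    pre_window: SpikeWindow,
    voltage_bitmap: np.ndarray,
    calcium_samples,
    params: VGParams,
    window_span: Optional[float] = None,
) -> np.ndarray:
    """Row-level voltage-gated update (contract form of the batched pass).

    ``voltage_bitmap`` maps each post id to a per-millisecond gate record
    (``V(t) > theta_V``) covering the window; ``calcium_samples`` is a
    callable ``(post_id, t) -> C(t)`` evaluable anywhere in the window.
    Jumps are applied at delay-shifted pre arrivals in chronological order,
    then the per-window drift, then clipping.
    """
    if voltage_bitmap is None:
        raise ValueError("voltage bitmap required when the voltage-gated rule is attached")
    t0 = pre_window.phase_start
    span = pre_window.window_span if window_span is None else window_span
    t1 = t0 + span
    centers = bin_centers(t0, pre_window.n_bins, pre_window.bin_ms)[pre_window.bits]
    w_start = row.weights.copy()
    dw = np.zeros(len(row.post_ids))
    for e, (j, d) in enumerate(zip(row.post_ids, row.delays)):
        arr = centers + d
        arr = arr[arr < t1]
        if arr.size == 0:
            continue
        k = np.asarray(np.floor(arr - t0), dtype=np.int64)
        gate = np.asarray(voltage_bitmap[j], dtype=bool)[k]
        c = np.asarray([calcium_samples(j, t) for t in arr])
        dw[e] = _vg_jump(gate, c, params).sum()
    dw += _vg_drift(w_start, span, params)
    row.weights[:] = np.clip(w_start + dw, params.w_min, params.w_max)
    return row.weights


# ==========================================================================
# rule registry
# ==========================================================================

_RULES = {
    "stdp_trace": (STDPRule, STDPParams),
    "bcm": (BCMRule, BCMParams),
    "vg_stdp": (VGRule, VGParams),
}


def make_rule(name: str, **kwargs):
    """Build a rule from its config name and flat parameter table."""
    if name not in _RULES:
        raise ValueError(f"unknown rule name {name!r}; choose from {sorted(_RULES)}")
    cls, pcls = _RULES[name]
    return cls(pcls(**kwargs))
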