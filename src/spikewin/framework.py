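"""Batched plasticity bookkeeping.

Spike histories are kept as double-buffered bitmaps: pre- and post-synaptic
spikes at 2 ms resolution over a 128 ms window (both configurable), exact
per-window post-spike counters for rate rules, and an optional 1 ms
voltage-gate bitmap.  While the simulation records into the active window,
the plasticity pass reads the completed (inactive) one; at every window
boundary the parities swap and the newly active window is cleared.

The weight-update pass walks every synaptic row of a plastic projection
exactly once per completed window, independent of activity, and records one
write-back per row (batched accounting).  Per-pre-spike (deferred event
driven) accounting is tracked alongside for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SpikeWindow",
    "DoubleBuffer",
    "WritebackLedger",
    "WindowView",
    "ProjectionPlasticState",
    "record_pre_spike",
    "swap_and_clear",
    "run_plasticity_pass",
    "count_writebacks",
    "windows_started",
]


class BufferingError(RuntimeError):
    """A spike was recorded outside the active window (a buffering bug)."""


def time_to_bin(t: float, phase_start: float, bin_ms: int, n_bins: int) -> int:
    b = int((t - phase_start) // bin_ms)
    if not 0 <= b < n_bins:
        raise BufferingError(
            f"spike at t={t} outside active window starting at {phase_start}"
        )
    return b


def bin_centers(t0: float, n_bins: int, bin_ms: int) -> np.ndarray:
    """Reconstruction times for bitmap bins: bin centers."""
    return t0 + bin_ms * np.arange(n_bins) + bin_ms / 2.0


# --------------------------------------------------------------------------
# single-neuron window objects (contract-level API; the simulator uses the
# vectorised stores below)
# --------------------------------------------------------------------------


@dataclass
class SpikeWindow:
    """Fixed-length spike-history bitmap: one bit per ``bin_ms`` bin over a
    ``window_span`` ms phase.  Multiple spikes in a bin collapse to one bit."""

    bin_ms: int = 2
    window_span: int = 128
    phase_start: float = 0.0
    parity: int = 0
    bits: np.ndarray = None

    def __post_init__(self):
        if self.window_span % self.bin_ms != 0:
            raise ValueError("window_span must be a multiple of bin_ms")
        if self.bits is None:
            self.bits = np.zeros(self.window_span // self.bin_ms, dtype=bool)

    @property
    def n_bins(self) -> int:
        return len(self.bits)

    def clear(self) -> None:
        self.bits[:] = False

    def spike_bins(self) -> np.ndarray:
        return np.flatnonzero(self.bits)


def record_pre_spike(window: SpikeWindow, t: float) -> SpikeWindow:
    """Set the bit for spike time ``t``; idempotent within a bin."""
    b = time_to_bin(t, window.phase_start, window.bin_ms, window.n_bins)
    window.bits[b] = True
    return window


@dataclass
class DoubleBuffer:
    """Two alternating spike windows: the active parity receives spikes,
    the other is read by the plasticity pass."""

    bin_ms: int = 2
    window_span: int = 128
    active_parity: int = 0
    windows: tuple = None

    def __post_init__(self):
        if self.windows is None:
            self.windows = (
                SpikeWindow(self.bin_ms, self.window_span, 0.0, 0),
                SpikeWindow(self.bin_ms, self.window_span, 0.0, 1),
            )

    @property
    def active(self) -> SpikeWindow:
        return self.windows[self.active_parity]

    @property
    def completed(self) -> SpikeWindow:
        return self.windows[1 - self.active_parity]

    def record(self, t: float) -> None:
        record_pre_spike(self.active, t)


def swap_and_clear(buffer: DoubleBuffer, boundary_t: float) -> DoubleBuffer:
    """Swap parities at a window boundary: the previously active window is
    preserved for the plasticity pass and the new active window is cleared
    and re-phased to ``boundary_t``."""
    buffer.active_parity ^= 1
    w = buffer.active
    w.clear()
    w.phase_start = boundary_t
    return buffer


# --------------------------------------------------------------------------
# write-back accounting
# --------------------------------------------------------------------------


class WritebackLedger:
    """Per-row write-back counters.

    ``batched`` mode increments once per row per completed plasticity
    window; ``ded`` (per-pre-spike) mode increments once per pre spike.
    Both are tracked so they can be compared on one run."""

    MODES = ("batched", "ded")

    def __init__(self, n_rows: int, mode: str = "batched"):
        if mode not in self.MODES:
            raise ValueError(f"ledger mode must be one of {self.MODES}")
        self.n_rows = int(n_rows)
        self.mode = mode
        self.batched_counts = np.zeros(n_rows, dtype=np.int64)
        self.ded_counts = np.zeros(n_rows, dtype=np.int64)

    def record_pass(self) -> None:
        self.batched_counts += 1

    def record_pre_spikes(self, pre_ids: np.ndarray) -> None:
        np.add.at(self.ded_counts, np.asarray(pre_ids, dtype=np.int64), 1)

    def counts(self, mode: Optional[str] = None) -> np.ndarray:
        mode = mode or self.mode
        if mode == "batched":
            return self.batched_counts.copy()
        if mode == "ded":
            return self.ded_counts.copy()
        raise ValueError(f"unknown ledger mode {mode!r}")


def windows_started(duration: int, window_ms: int) -> int:
    """Number of plasticity windows starting within [0, duration)."""
    if duration <= 0:
        return 0
    return (duration - 1) // window_ms + 1


def count_writebacks(
    mode: str,
    duration: int,
    pre_spike_times: Sequence[float] = (),
    window_ms: int = 128,
) -> int:
    """Analytic per-row write-back count for a run of ``duration`` ms."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if mode == "batched":
        return windows_started(duration, window_ms)
    if mode == "ded":
        return int(np.count_nonzero(np.asarray(pre_spike_times) < duration))
    raise ValueError(f"unknown ledger mode {mode!r}")


# --------------------------------------------------------------------------
# vectorised per-projection state used by the simulator
# --------------------------------------------------------------------------


@dataclass
class WindowView:
    """Read-only view of one completed plasticity window."""

    t0: float
    t1: float
    bin_ms: int
    pre_bits: np.ndarray           # (n_pre, n_bins) bool
    post_bits: np.ndarray          # (n_post, n_bins) bool
    post_counts: np.ndarray        # (n_post,) exact spike counts
    v_bits: Optional[np.ndarray]   # (n_post, window_ms) bool, 1 ms resolution

    @property
    def span(self) -> float:
        return self.t1 - self.t0

    def post_events(self) -> tuple[np.ndarray, np.ndarray]:
        """(post_idx, times) of post spikes reconstructed at bin centers."""
        j, b = np.nonzero(self.post_bits)
        return j, self.t0 + self.bin_ms * b + self.bin_ms / 2.0

    def voltage_at(self, post_idx: np.ndarray, times: np.ndarray) -> np.ndarray:
        """Gate bit V(t) > theta_V at integer-ms ``times`` within the window."""
        if self.v_bits is None:
            raise ValueError("voltage bitmap not recorded for this projection")
        k = np.asarray(np.floor(times - self.t0), dtype=np.int64)
        if k.size and (k.min() < 0 or k.max() >= self.v_bits.shape[1]):
            raise BufferingError("voltage lookup outside the completed window")
        return self.v_bits[post_idx, k]


class ProjectionPlasticState:
    """Double-buffered spike histories and rule state for one plastic
    projection, plus the mechanism that turns pre-spike bitmap bins into
    delay-shifted arrival events (arrivals falling past the window end are
    deferred to the next pass)."""

    def __init__(self, proj, window_ms: int = 128, bin_ms: int = 2):
        if window_ms % bin_ms != 0:
            raise ValueError("window_ms must be a multiple of bin_ms")
        self.proj = proj
        self.window_ms = int(window_ms)
        self.bin_ms = int(bin_ms)
        self.n_bins = window_ms // bin_ms
        n_pre, n_post = proj.pre.size, proj.post.size
        self.pre_bits = np.zeros((2, n_pre, self.n_bins), dtype=bool)
        self.post_bits = np.zeros((2, n_post, self.n_bins), dtype=bool)
        self.post_counts = np.zeros((2, n_post), dtype=np.int64)
        self.needs_voltage = bool(getattr(proj.rule, "needs_voltage", False))
        self.v_bits = (
            np.zeros((2, n_post, self.window_ms), dtype=bool)
            if self.needs_voltage else None
        )
        self.active = 0
        self.phase_start = 0.0
        self.ledger = WritebackLedger(n_pre)
        self.pending_entry = np.empty(0, dtype=np.int64)
        self.pending_times = np.empty(0, dtype=np.float64)
        self.rule_state = proj.rule.init_state(proj)

    # -- recording (active window) ----------------------------------------

    def _bin(self, t: float) -> int:
        return time_to_bin(t, self.phase_start, self.bin_ms, self.n_bins)

    def record_pre(self, pre_ids: np.ndarray, t: float) -> None:
        self.pre_bits[self.active, pre_ids, self._bin(t)] = True
        self.ledger.record_pre_spikes(pre_ids)

    def record_post(self, post_ids: np.ndarray, t: float) -> None:
        self.post_bits[self.active, post_ids, self._bin(t)] = True
        np.add.at(self.post_counts[self.active], post_ids, 1)

    def record_voltage(self, v: np.ndarray, t: float) -> None:
        k = int(t - self.phase_start)
        if not 0 <= k < self.window_ms:
            raise BufferingError(f"voltage sample at t={t} outside active window")
        self.v_bits[self.active, :, k] = v > self.proj.rule.theta_v

    # -- boundary ----------------------------------------------------------

    def swap(self, boundary_t: float) -> WindowView:
        """Swap buffers at ``boundary_t`` and return the completed window."""
        completed = self.active
        t0, t1 = self.phase_start, boundary_t
        self.active ^= 1
        self.pre_bits[self.active] = False
        self.post_bits[self.active] = False
        self.post_counts[self.active] = 0
        if self.v_bits is not None:
            self.v_bits[self.active] = False
        self.phase_start = boundary_t
        return WindowView(
            t0, t1, self.bin_ms,
            self.pre_bits[completed], self.post_bits[completed],
            self.post_counts[completed],
            self.v_bits[completed] if self.v_bits is not None else None,
        )

    def run_pass(self, boundary_t: float) -> None:
        view = self.swap(boundary_t)
        run_plasticity_pass(self.proj.rule, self.proj, self, view)

    # -- arrival events ----------------------------------------------------

    def take_arrivals(self, view: WindowView) -> tuple[np.ndarray, np.ndarray]:
        """Delay-shifted pre-spike arrival events due within this window.

        Pre spike times are reconstructed at bin centers and shifted by each
        entry's delay; arrivals at or beyond ``view.t1`` are queued for the
        next pass.  Returns ``(entry_idx, arrival_times)`` sorted by time.
        """
        proj = self.proj
        nz_pre, nz_bin = np.nonzero(view.pre_bits)
        centers = view.t0 + self.bin_ms * nz_bin + self.bin_ms / 2.0
        lo = proj.indptr[nz_pre]
        reps = proj.indptr[nz_pre + 1] - lo
        total = int(reps.sum())
        if total:
            offs = np.repeat(np.cumsum(reps) - reps, reps)
            eidx = np.arange(total) - offs + np.repeat(lo, reps)
            times = np.repeat(centers, reps) + proj.delays[eidx]
        else:
            eidx = np.empty(0, dtype=np.int64)
            times = np.empty(0, dtype=np.float64)
        eidx = np.concatenate([self.pending_entry, eidx])
        times = np.concatenate([self.pending_times, times])
        due = times < view.t1
        self.pending_entry = eidx[~due]
        self.pending_times = times[~due]
        eidx, times = eidx[due], times[due]
        order = np.argsort(times, kind="stable")
        return eidx[order], times[order]


def run_plasticity_pass(rule, proj, state: ProjectionPlasticState, view: WindowView) -> None:
    """Apply ``rule`` to every row of ``proj`` for one completed window.

    The rule returns updated (unclipped) weights for all entries; they are
    clipped to the rule's bounds here.  One write-back per row is recorded
    regardless of activity: the pass always runs.
    """
    new_w = rule.process_window(proj, state, view)
    np.clip(new_w, rule.w_min, rule.w_max, out=new_w)
    proj.weights[:] = new_w
    state.ledger.record_pass()
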