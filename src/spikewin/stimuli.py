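"""Synthetic stimulus generators.

All generators are pure functions of their spec and an explicit
``numpy.random.Generator``; identical inputs give identical spike trains.
Spike times are integer milliseconds, matching the 1 ms engine resolution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "PoissonSpec",
    "BarStimulus",
    "SweepPattern",
    "poisson_train",
    "regular_train",
    "teacher_protocol",
    "burst_times",
    "bar_image",
    "rates",
    "bar_poisson_trains",
    "sweep_spikes",
]


# --------------------------------------------------------------------------
# Poisson sources
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PoissonSpec:
    rate: float            # Hz
    start: int = 0         # ms
    stop: int = 1000       # ms
    n_sources: int = 1

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.start >= self.stop:
            raise ValueError("start must precede stop")


def poisson_train(spec: PoissonSpec, rng: np.random.Generator) -> list[np.ndarray]:
    """Per-millisecond Bernoulli thinning at p = rate/1000 (capped at 1).

    Returns one sorted integer spike-time array per source.
    """
    p = spec.rate / 1000.0
    if p > 1.0:
        warnings.warn(f"rate {spec.rate} Hz exceeds 1 spike/ms; capping", stacklevel=2)
        p = 1.0
    n_ms = spec.stop - spec.start
    trains: list[np.ndarray] = []
    # chunk the Bernoulli matrix over time to bound memory
    chunk = max(1, min(n_ms, (1 << 23) // max(1, spec.n_sources)))
    parts: list[list[np.ndarray]] = [[] for _ in range(spec.n_sources)]
    for off in range(0, n_ms, chunk):
        width = min(chunk, n_ms - off)
        draws = rng.random((spec.n_sources, width)) < p
        src, t = np.nonzero(draws)
        t = t + spec.start + off
        for i in range(spec.n_sources):
            parts[i].append(t[src == i])
    for i in range(spec.n_sources):
        trains.append(
            np.concatenate(parts[i]) if parts[i] else np.empty(0, dtype=np.int64)
        )
    return trains


def regular_train(rate: float, duration: int, start: int = 0) -> np.ndarray:
    """Evenly spaced spikes at ``rate`` Hz over ``[start, start+duration)``."""
    if rate <= 0:
        return np.empty(0, dtype=np.int64)
    n = int(math.floor(rate * duration / 1000.0))
    times = start + np.floor(np.arange(n) * 1000.0 / rate).astype(np.int64)
    return times[times < start + duration]


# --------------------------------------------------------------------------
# teacher pairing protocol
# --------------------------------------------------------------------------


def burst_times(
    onsets: Sequence[int],
    rng: np.random.Generator,
    burst_rate: float = 350.0,
    burst_ms: int = 20,
) -> np.ndarray:
    """High-frequency Poisson bursts: ``burst_rate`` Hz for ``burst_ms`` ms
    after each onset.  Returns a single merged, sorted spike-time array."""
    out = []
    p = min(1.0, burst_rate / 1000.0)
    for onset in onsets:
        hit = rng.random(burst_ms) < p
        out.append(onset + np.flatnonzero(hit))
    return np.sort(np.concatenate(out)) if out else np.empty(0, dtype=np.int64)


def teacher_protocol(
    stim_onsets: Sequence[int],
    target_lag: int,
    rng: np.random.Generator,
    burst_rate: float = 350.0,
    burst_ms: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired burst schedules: target bursts are stimulus bursts shifted by
    ``target_lag`` ms (>= 0), each realised as an independent Poisson burst."""
    if target_lag < 0:
        raise ValueError("target_lag must be >= 0")
    stim_onsets = np.asarray(stim_onsets, dtype=np.int64)
    stim = burst_times(stim_onsets, rng, burst_rate, burst_ms)
    target = burst_times(stim_onsets + target_lag, rng, burst_rate, burst_ms)
    return stim, target


# --------------------------------------------------------------------------
# oriented bars
# --------------------------------------------------------------------------


@dataclass
class BarStimulus:
    image: np.ndarray          # (grid, grid) intensities in [0, 1]
    angle: float               # degrees
    total_rate: float          # Hz summed over pixels

    @property
    def on_pixels(self) -> np.ndarray:
        return self.image > 0


def bar_image(
    angle: float,
    rng: np.random.Generator,
    grid: int = 16,
    thickness: float = 3.0,
    length: float = 12.0,
    total_rate: float = 1000.0,
) -> BarStimulus:
    """Oriented bar on a ``grid x grid`` intensity image.

    The bar is centred, ``thickness`` px thick and ``length`` px long;
    on-bar pixel intensities are drawn uniformly from [0.8, 1.0], off-bar
    pixels are 0.  A pixel is on the bar if its centre lies within the
    bar rectangle (nearest-pixel rasterisation).
    """
    theta = math.radians(angle)
    ux, uy = math.cos(theta), math.sin(theta)
    # integer grid centre so an odd thickness rasterises symmetrically
    c = grid // 2
    ii, jj = np.meshgrid(np.arange(grid), np.arange(grid), indexing="ij")
    # x along columns, y along rows (sign irrelevant by symmetry)
    dx, dy = jj - c, ii - c
    along = dx * ux + dy * uy
    perp = -dx * uy + dy * ux
    tol = 1e-9  # guards against inexact trig zeros at axis-aligned angles
    on = (np.abs(along) <= (length - 1) / 2.0 + tol) & (
        np.abs(perp) <= (thickness - 1) / 2.0 + tol
    )
    image = np.zeros((grid, grid))
    image[on] = 0.8 + 0.2 * rng.random(int(on.sum()))
    return BarStimulus(image=image, angle=angle % 360.0, total_rate=total_rate)


def rates(image: np.ndarray, total_rate: float) -> np.ndarray:
    """Per-pixel firing rates proportional to intensity, scaled so the
    rates sum to ``total_rate`` Hz (all zeros stay all zeros)."""
    image = np.asarray(image, dtype=np.float64)
    s = image.sum()
    if s == 0:
        return np.zeros_like(image)
    return image * (total_rate / s)


def bar_poisson_trains(
    stim: BarStimulus,
    duration: int,
    rng: np.random.Generator,
    start: int = 0,
) -> list[np.ndarray]:
    """Convert a bar image into per-pixel Poisson spike trains (row-major
    pixel order), over ``[start, start + duration)``."""
    r = rates(stim.image, stim.total_rate).ravel()
    p = np.minimum(r / 1000.0, 1.0)
    draws = rng.random((len(r), duration)) < p[:, None]
    return [start + np.flatnonzero(draws[i]) for i in range(len(r))]


# --------------------------------------------------------------------------
# tonotopic frequency sweeps
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SweepPattern:
    kind: str                   # forward | backward | forked
    n_channels: int = 16
    inter_channel_dt: int = 10  # ms
    repeat_gap: int = 300       # ms between presentation onsets
    repeats: int = 1

    def __post_init__(self):
        if self.kind not in ("forward", "backward", "forked"):
            raise ValueError("kind must be forward, backward or forked")
        if self.n_channels < 3:
            raise ValueError("need at least 3 channels")


def _single_sweep_offsets(pattern: SweepPattern) -> np.ndarray:
    """Per-channel spike offset (ms) within one presentation."""
    n, dt = pattern.n_channels, pattern.inter_channel_dt
    k = np.arange(n)
    if pattern.kind == "forward":
        return k * dt
    if pattern.kind == "backward":
        return (n - 1 - k) * dt
    mid = (n - 1) // 2  # forked: middle channel first, mirror pairs outward
    return np.abs(k - mid) * dt


def sweep_spikes(pattern: SweepPattern) -> list[np.ndarray]:
    """Per-channel spike times for a repeated frequency sweep."""
    offsets = _single_sweep_offsets(pattern)
    onsets = np.arange(pattern.repeats) * pattern.repeat_gap
    return [
        (onsets[:, None] + offsets[ch]).ravel().astype(np.int64)
        for ch in range(pattern.n_channels)
    ]
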