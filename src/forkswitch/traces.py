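"""Single-molecule trace analysis.

Gamma calibration from acceptor photobleaching, intensity-to-FRET conversion,
velocity-gated segmentation into unwinding / rezipping / pause intervals,
per-state FRET distributions, and dwell-time kinetics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fret import kde_distribution, peak_positions

__all__ = [
    "SMTrace",
    "BleachEvent",
    "Interval",
    "StateIntervals",
    "RateEstimates",
    "GammaEstimate",
    "UNWINDING",
    "REZIPPING",
    "PAUSE",
    "estimate_gamma",
    "fret_from_intensities",
    "sliding_velocity",
    "segment_states",
    "fret_by_state",
    "dwell_and_rates",
]

UNWINDING = "unwinding"
REZIPPING = "rezipping"
PAUSE = "pause"


@dataclass
class SMTrace:
    """Synchronized tweezer + FRET time series.

    ``time`` in seconds (strictly increasing, uniform), ``position`` in base
    pairs, intensities in arbitrary (non-negative) units.  ``true_states`` is
    an optional per-sample ground-truth state label array from a generator.
    """

    time: np.ndarray
    position: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    sampling_rate: float | None = None
    true_states: np.ndarray | None = None
    true_switch_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        n = self.time.size
        if any(a.size != n for a in (self.position, self.donor, self.acceptor)):
            raise ValueError("trace columns differ in length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.donor < 0) or np.any(self.acceptor < 0):
            raise ValueError("intensities must be non-negative")
        if self.sampling_rate is None and n > 1:
            self.sampling_rate = 1.0 / float(np.median(np.diff(self.time)))

    def __len__(self) -> int:
        return self.time.size

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate


@dataclass
class BleachEvent:
    """A donor/acceptor intensity pair around one acceptor photobleach step."""

    time: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    bleach_time: float


@dataclass(frozen=True)
class Interval:
    start: float
    end: float
    label: str
    velocity: float  # mean fitted velocity, bp/s

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class StateIntervals:
    """Non-overlapping, time-ordered state intervals covering the trace."""

    intervals: list[Interval]

    def __post_init__(self) -> None:
        for a, b in zip(self.intervals, self.intervals[1:]):
            if b.start < a.end - 1e-12:
                raise ValueError("intervals overlap or are unordered")

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def of_label(self, label: str) -> list[Interval]:
        return [iv for iv in self.intervals if iv.label == label]


@dataclass
class RateEstimates:
    """Inverse-mean-dwell rates and the equilibrium constant k_u2r / k_r2u."""

    k_u2r: float | None
    k_r2u: float | None
    mean_dwell_unwind: float | None
    mean_dwell_rezip: float | None
    n_dwell_unwind: int
    n_dwell_rezip: int

    @property
    def keq(self) -> float | None:
        if self.k_u2r is None or self.k_r2u is None or self.k_r2u == 0:
            return None
        return self.k_u2r / self.k_r2u


@dataclass
class GammaEstimate:
    gamma: float
    per_event: list[float]
    n_excluded: int = 0

    def __float__(self) -> float:
        return self.gamma


# ---------------------------------------------------------------------------
# gamma calibration
# ---------------------------------------------------------------------------

def estimate_gamma(events: Sequence[BleachEvent]) -> GammaEstimate:
    """Detection-efficiency ratio gamma = dIA/dID from acceptor bleach steps.

    Per event, dIA = mean acceptor before minus after the bleach and dID =
    mean donor after minus before; gamma is the mean of the per-event ratios.
    Events with non-positive donor step are excluded with a warning.
    """
    if len(events) == 0:
        raise ValueError("need at least one bleach event")
    ratios: list[float] = []
    excluded = 0
    for ev in events:
        t = np.asarray(ev.time, dtype=float)
        pre = t < ev.bleach_time
        post = t > ev.bleach_time
        if not pre.any() or not post.any():
            raise ValueError("bleach time leaves an empty pre or post window")
        d_ia = float(np.mean(ev.acceptor[pre]) - np.mean(ev.acceptor[post]))
        d_id = float(np.mean(ev.donor[post]) - np.mean(ev.donor[pre]))
        if d_id <= 0:
            excluded += 1
            warnings.warn("bleach event with non-positive donor step excluded")
            continue
        ratios.append(d_ia / d_id)
    if not ratios:
        raise ValueError("all bleach events excluded")
    return GammaEstimate(gamma=float(np.mean(ratios)), per_event=ratios,
                         n_excluded=excluded)


# ---------------------------------------------------------------------------
# FRET from intensities
# ---------------------------------------------------------------------------

def fret_from_intensities(
    trace: SMTrace,
    gamma: float = 0.78,
    integration: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """E(t) = 1 / (1 + gamma * ID/IA), on block-averaged intensities.

    Intensities are first averaged over ``integration`` consecutive samples,
    then E is computed per block; blocks with zero acceptor signal are NaN.
    Returns ``(block_center_times, E)``.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if integration < 1:
        raise ValueError("integration must be >= 1 sample")
    n = len(trace) // integration
    if n == 0:
        raise ValueError("trace shorter than one integration window")
    m = n * integration
    t = trace.time[:m].reshape(n, integration).mean(axis=1)
    i_d = trace.donor[:m].reshape(n, integration).mean(axis=1)
    i_a = trace.acceptor[:m].reshape(n, integration).mean(axis=1)
    e = np.full(n, np.nan)
    ok = i_a > 0
    e[ok] = 1.0 / (1.0 + gamma * i_d[ok] / i_a[ok])
    return t, e


# ---------------------------------------------------------------------------
# velocity-gated segmentation
# ---------------------------------------------------------------------------

def sliding_velocity(trace: SMTrace, window: float = 0.25) -> np.ndarray:
    """Per-point velocity (bp/s) by linear fit over a centered sliding window.

    ``window`` is in seconds; edge points reuse the nearest full-window fit.
    """
    dt = trace.dt
    w = max(2, int(round(window / dt)) | 1)  # odd, >= 3 effectively
    if w > len(trace):
        raise ValueError("velocity window longer than trace")
    h = w // 2
    k = np.arange(-h, h + 1, dtype=float)
    denom = dt * np.sum(k * k)
    # slope_i = sum_j (j - i) * x_j / (dt * sum k^2) over the centered window
    v_valid = np.convolve(trace.position, -k / denom, mode="valid")
    v = np.empty(len(trace))
    v[h:len(trace) - h] = v_valid
    v[:h] = v_valid[0]
    v[len(trace) - h:] = v_valid[-1]
    return v


def _label_points(v: np.ndarray, pause_threshold: float) -> np.ndarray:
    labels = np.where(v > 0, UNWINDING, REZIPPING).astype(object)
    labels[np.abs(v) < pause_threshold] = PAUSE
    return labels


def segment_states(
    trace: SMTrace,
    pause_threshold: float = 20.0,
    velocity_window: float = 0.25,
    min_duration: float = 0.0,
) -> StateIntervals:
    """Label each sample unwinding / rezipping / pause and merge into intervals.

    Velocity comes from :func:`sliding_velocity`; a point pauses when
    ``|v| < pause_threshold`` (bp/s), otherwise the sign of v decides the
    state.  Runs shorter than ``min_duration`` seconds are merged into their
    longer neighbor.
    """
    if trace.time[-1] - trace.time[0] <= velocity_window:
        raise ValueError("trace span must exceed the velocity window")
    v = sliding_velocity(trace, velocity_window)
    labels = _label_points(v, pause_threshold)
    dt = trace.dt

    runs: list[list] = []  # [label, start_idx, end_idx) half-open
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append([labels[start], start, i])
            start = i

    if min_duration > 0 and len(runs) > 1:
        changed = True
        while changed and len(runs) > 1:
            changed = False
            durations = [(r[2] - r[1]) * dt for r in runs]
            j = int(np.argmin(durations))
            if durations[j] < min_duration:
                neighbors = []
                if j > 0:
                    neighbors.append(j - 1)
                if j < len(runs) - 1:
                    neighbors.append(j + 1)
                tgt = max(neighbors, key=lambda i: runs[i][2] - runs[i][1])
                lo, hi = min(j, tgt), max(j, tgt)
                runs[lo] = [runs[tgt][0], runs[lo][1], runs[hi][2]]
                del runs[hi]
                changed = True
        # re-merge adjacent runs that now share a label
        merged = [runs[0]]
        for r in runs[1:]:
            if r[0] == merged[-1][0]:
                merged[-1][2] = r[2]
            else:
                merged.append(r)
        runs = merged

    t0 = trace.time[0]
    intervals = []
    for label, i, j in runs:
        t_start = trace.time[i] if i > 0 else t0
        t_end = trace.time[j] if j < len(trace) else trace.time[-1] + dt
        intervals.append(
            Interval(start=float(t_start), end=float(t_end), label=str(label),
                     velocity=float(np.mean(v[i:j])))
        )
    return StateIntervals(intervals=intervals)


# ---------------------------------------------------------------------------
# per-state FRET distributions
# ---------------------------------------------------------------------------

def fret_by_state(
    times: np.ndarray,
    efficiencies: np.ndarray,
    intervals: StateIntervals,
    sigma: float = 0.06,
    min_prominence: float = 0.05,
) -> dict:
    """Collect E points inside non-pause intervals and KDE them per state.

    Returns ``{label: {"values", "grid", "density", "peaks"}}`` for the
    unwinding and rezipping states; a state with no points maps to None.
    """
    times = np.asarray(times, dtype=float)
    efficiencies = np.asarray(efficiencies, dtype=float)
    by_state: dict[str, list[float]] = {UNWINDING: [], REZIPPING: []}
    for iv in intervals:
        if iv.label == PAUSE:
            continue
        sel = (times >= iv.start) & (times < iv.end) & np.isfinite(efficiencies)
        by_state[iv.label].extend(efficiencies[sel].tolist())

    out: dict = {}
    for label, vals in by_state.items():
        if not vals:
            warnings.warn(f"no FRET points in {label} state")
            out[label] = None
            continue
        grid, dens = kde_distribution(vals, sigma=sigma)
        out[label] = {
            "values": np.asarray(vals),
            "grid": grid,
            "density": dens,
            "peaks": peak_positions(grid, dens, min_prominence=min_prominence),
        }
    return out


# ---------------------------------------------------------------------------
# dwell times and rates
# ---------------------------------------------------------------------------

def dwell_and_rates(intervals: StateIntervals) -> RateEstimates:
    """Rates as inverse mean dwell times over complete (uncensored) dwells.

    A dwell is the duration of a non-pause interval bounded by transitions on
    both sides; the first and last intervals of the analyzed span are censored
    and excluded.  Keq = k_u2r / k_r2u.
    """
    ivs = intervals.intervals
    dwells: dict[str, list[float]] = {UNWINDING: [], REZIPPING: []}
    for pos, iv in enumerate(ivs):
        if iv.label == PAUSE:
            continue
        if pos == 0 or pos == len(ivs) - 1:
            continue  # censored at the trace boundary
        dwells[iv.label].append(iv.duration)

    def _rate(key):
        vals = dwells[key]
        if not vals:
            return None, None
        mean = float(np.mean(vals))
        return (1.0 / mean if mean > 0 else None), mean

    k_u, mean_u = _rate(UNWINDING)
    k_r, mean_r = _rate(REZIPPING)
    return RateEstimates(
        k_u2r=k_u,
        k_r2u=k_r,
        mean_dwell_unwind=mean_u,
        mean_dwell_rezip=mean_r,
        n_dwell_unwind=len(dwells[UNWINDING]),
        n_dwell_rezip=len(dwells[REZIPPING]),
    )
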