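"""Desk-scale Hamiltonian replica exchange.

M overdamped Langevin walkers evolve on one analytic potential, each under a
harmonic window bias; every exchange interval, neighboring bias windows
attempt a Metropolis configuration swap.  Samples are recorded per WINDOW
(bias), so with exchanges disabled the run reduces exactly to independent
umbrella sampling with the same per-replica noise streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .potentials import AnalyticPotential
from .synthetic_data import BURN_IN_FRACTION

__all__ = [
    "BiasLadder",
    "WindowSamples",
    "make_ladder",
    "run_hrex",
    "exchange_acceptance",
]


@dataclass(frozen=True)
class BiasLadder:
    """An ordered ladder of harmonic window biases on the reaction coordinate."""

    centers: tuple          # p_m, strictly increasing
    springs: tuple          # k_m > 0
    exchange_interval: int  # steps between swap attempts; 0 disables exchanges
    kT: float = 1.0

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, dtype=float)
        k = np.asarray(self.springs, dtype=float)
        if c.size < 2:
            raise ValueError("ladder needs at least 2 windows")
        if np.any(np.diff(c) <= 0):
            raise ValueError("window centers must be strictly increasing")
        if k.size != c.size:
            raise ValueError("one spring constant per window required")
        if np.any(k <= 0):
            raise ValueError("spring constants must be positive")
        if self.kT <= 0:
            raise ValueError("kT must be positive")

    @property
    def n_windows(self) -> int:
        return len(self.centers)


@dataclass
class WindowSamples:
    """Per-window reaction-coordinate samples with their bias parameters.

    ``samples[m]`` has shape ``(n,)`` for a 1D potential or ``(n, 2)`` when a
    second (unbiased) coordinate is recorded alongside.  ``acceptance`` maps
    neighbor pair ``(m, m+1)`` to its swap acceptance rate.
    """

    centers: np.ndarray
    springs: np.ndarray
    kT: float
    samples: list = field(default_factory=list)
    acceptance: dict = field(default_factory=dict)
    n_attempted: dict = field(default_factory=dict)
    # per-walker (min, max) window index visited; walker identity follows the
    # configuration through swaps
    walker_range: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.springs = np.asarray(self.springs, dtype=float)
        if np.any(np.diff(self.centers) <= 0):
            raise ValueError("windows must be ordered by center")
        for s in self.samples:
            if not np.all(np.isfinite(s)):
                raise ValueError("non-finite sample")

    @property
    def n_windows(self) -> int:
        return len(self.centers)

    def coordinate(self, m: int) -> np.ndarray:
        """The biased (first) coordinate of window m."""
        s = np.asarray(self.samples[m])
        return s if s.ndim == 1 else s[:, 0]


def make_ladder(
    xi_start: float,
    xi_end: float,
    n_windows: int,
    spring: float = 100.0,
    exchange_interval: int = 200,
    kT: float = 1.0,
) -> BiasLadder:
    """Uniformly spaced window centers inclusive of both endpoints."""
    if n_windows < 2:
        raise ValueError("need at least 2 windows")
    if xi_end <= xi_start:
        raise ValueError("descending or degenerate endpoints rejected")
    centers = np.linspace(xi_start, xi_end, n_windows)
    return BiasLadder(
        centers=tuple(centers),
        springs=tuple([float(spring)] * n_windows),
        exchange_interval=int(exchange_interval),
        kT=float(kT),
    )


def exchange_acceptance(
    xi_m: float, xi_n: float,
    center_m: float, spring_m: float,
    center_n: float, spring_n: float,
    kT: float,
) -> float:
    """Metropolis probability of swapping configurations between windows m, n.

    Symmetric in the pair: swapping the argument order gives the same value.
    """
    def u(center, spring, xi):
        return 0.5 * spring * (xi - center) ** 2

    delta = (
        u(center_m, spring_m, xi_n) + u(center_n, spring_n, xi_m)
        - u(center_m, spring_m, xi_m) - u(center_n, spring_n, xi_n)
    )
    return float(min(1.0, np.exp(-delta / kT)))


def run_hrex(
    potential: AnalyticPotential,
    ladder: BiasLadder,
    n_steps: int = 50_000,
    dt: float = 5e-3,
    friction: float = 1.0,
    seed: int | None = None,
    sample_every: int = 20,
    x0: Sequence[float] | None = None,
) -> WindowSamples:
    """Run M biased walkers with periodic neighbor configuration swaps.

    Each replica keeps its own RNG stream (spawned from ``seed``), so a run
    with ``exchange_interval = 0`` is bit-identical to M independent umbrella
    samplers.  Swap attempts alternate between even (0-1, 2-3, ...) and odd
    (1-2, 3-4, ...) neighbor pairings.  Samples are recorded per window every
    ``sample_every`` steps after a 10% burn-in; for a 2D potential the second
    (unbiased) coordinate is recorded alongside the first.
    """
    M = ladder.n_windows
    centers = np.asarray(ladder.centers, dtype=float)
    springs = np.asarray(ladder.springs, dtype=float)
    kT = ladder.kT
    dim = potential.dim

    seeds = np.random.SeedSequence(seed).spawn(M + 1)
    rngs = [np.random.default_rng(s) for s in seeds[:M]]
    swap_rng = np.random.default_rng(seeds[M])

    if x0 is None:
        x = centers.copy() if dim == 1 else np.column_stack(
            [centers, np.zeros(M)]
        )
    else:
        x = np.asarray(x0, dtype=float).copy()
        if dim == 1 and x.shape != (M,):
            raise ValueError("x0 must have one value per window")

    sigma = np.sqrt(2.0 * kT * dt / friction)
    mob = dt / friction
    burn = int(BURN_IN_FRACTION * n_steps)
    interval = ladder.exchange_interval if ladder.exchange_interval else n_steps + 1

    samples: list[list] = [[] for _ in range(M)]
    attempted: dict = {}
    accepted: dict = {}
    parity = 0
    walker = np.arange(M)            # walker id currently held by each window
    w_min = np.arange(M)
    w_max = np.arange(M)

    # Leimkuhler-Matthews overdamped step, one noise stream per replica
    prev = np.stack([
        r.standard_normal() if dim == 1 else r.standard_normal(dim) for r in rngs
    ])
    step = 0
    block = max(1, min(interval, 10_000))
    # overflow during a diverging trajectory is expected right before the
    # explicit failure below; silence the intermediate warnings only
    with np.errstate(over="ignore", invalid="ignore"):
        while step < n_steps:
            nblk = min(block, n_steps - step,
                       interval - (step % interval) or interval)
            noise = np.stack([
                r.standard_normal(nblk if dim == 1 else (nblk, dim))
                for r in rngs
            ])
            for i in range(nblk):
                if dim == 1:
                    g = potential.gradient(x) + springs * (x - centers)
                    x = x - mob * g + 0.5 * sigma * (prev + noise[:, i])
                else:
                    g = np.asarray(potential.gradient(x), dtype=float)
                    g[:, 0] += springs * (x[:, 0] - centers)
                    x = x - mob * g + 0.5 * sigma * (prev + noise[:, i])
                prev = noise[:, i]
                step += 1
                if step > burn and step % sample_every == 0:
                    for m in range(M):
                        samples[m].append(np.array(x[m], ndmin=0, copy=True))
            probe = x if dim == 1 else x[:, 0]
            if not np.all(np.isfinite(probe)) or np.any(np.abs(probe) > 1e8):
                bad = int(np.argmax(~np.isfinite(probe)
                                    | (np.abs(probe) > 1e8)))
                raise RuntimeError(
                    f"replica {bad} diverged by step {step} (dt={dt} too large?)"
                )
            if step % interval == 0 and step < n_steps:
                first = parity % 2
                for m in range(first, M - 1, 2):
                    xi_m = x[m] if dim == 1 else x[m, 0]
                    xi_n = x[m + 1] if dim == 1 else x[m + 1, 0]
                    p = exchange_acceptance(
                        float(xi_m), float(xi_n),
                        centers[m], springs[m],
                        centers[m + 1], springs[m + 1], kT,
                    )
                    key = (m, m + 1)
                    attempted[key] = attempted.get(key, 0) + 1
                    if swap_rng.random() < p:
                        accepted[key] = accepted.get(key, 0) + 1
                        tmp = np.array(x[m], copy=True)
                        x[m] = x[m + 1]
                        x[m + 1] = tmp
                        walker[m], walker[m + 1] = walker[m + 1], walker[m]
                        for w_pos, win in ((walker[m], m),
                                           (walker[m + 1], m + 1)):
                            w_min[w_pos] = min(w_min[w_pos], win)
                            w_max[w_pos] = max(w_max[w_pos], win)
                parity += 1

    acc_rate = {
        k: accepted.get(k, 0) / attempted[k] for k in attempted
    }
    return WindowSamples(
        centers=centers,
        springs=springs,
        kT=kT,
        samples=[np.asarray(s) for s in samples],
        acceptance=acc_rate,
        n_attempted=attempted,
        walker_range=np.column_stack([w_min, w_max]),
    )
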