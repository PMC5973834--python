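"""Synthetic-data generators with known ground truth.

Everything the analysis pipeline consumes can be produced here: structural
ensembles with planted motion modes, Boltzmann samples of analytic potentials
under harmonic window biases, dye dipole trajectories with controlled
distance/orientation statistics, two-state telegraph traces, and acceptor
photobleaching events.  Ground truth (planted modes, state paths, bleach
times) is always returned alongside the data so every downstream estimator
has an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fret import DyeTrajectory
from .potentials import AnalyticPotential
from .structures import StructureEnsemble
from .traces import BleachEvent, SMTrace, REZIPPING, UNWINDING

__all__ = [
    "DomainScaffold",
    "PlantedEnsemble",
    "TelegraphSpec",
    "demo_scaffold",
    "gen_domain_ensemble",
    "sample_biased",
    "gen_two_state_trace",
    "gen_photobleach_events",
    "gen_dye_trajectory",
]

BURN_IN_FRACTION = 0.1  # fixed: first 10% of steps discarded


# ---------------------------------------------------------------------------
# structural ensembles with planted modes
# ---------------------------------------------------------------------------

@dataclass
class DomainScaffold:
    """A C-alpha point set partitioned into named domains, one mobile."""

    coords: np.ndarray            # (N, 3)
    domain_labels: list[str]      # per atom
    mobile: str

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.domain_labels) != len(self.coords):
            raise ValueError("one domain label per atom required")
        doms = set(self.domain_labels)
        if len(doms) < 2:
            raise ValueError("scaffold needs at least 2 domains")
        if self.mobile not in doms:
            raise ValueError(f"mobile domain {self.mobile!r} not in {doms}")
        for d in doms:
            pts = self.coords[[l == d for l in self.domain_labels]]
            if len(pts) < 3 or np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
                raise ValueError(f"domain {d!r} degenerate: needs >=3 non-collinear atoms")

    @property
    def mobile_mask(self) -> np.ndarray:
        return np.array([l == self.mobile for l in self.domain_labels], dtype=bool)


@dataclass
class PlantedEnsemble:
    """Generated ensemble plus its planted ground truth."""

    ensemble: StructureEnsemble
    mode_directions: np.ndarray   # (2, 3 * n_mobile) unit vectors, mobile subset
    hinge: np.ndarray
    axes: np.ndarray              # (2, 3) rotation / tilt axes


def demo_scaffold(n_static: int = 30, n_mobile: int = 20, seed: int = 0) -> DomainScaffold:
    """A two-domain toy scaffold: a static core and a displaced mobile blob."""
    rng = np.random.default_rng(seed)
    static = rng.normal(scale=5.0, size=(n_static, 3))
    mobile = rng.normal(scale=4.0, size=(n_mobile, 3)) + np.array([18.0, 0.0, 0.0])
    return DomainScaffold(
        coords=np.vstack([static, mobile]),
        domain_labels=["core"] * n_static + ["mobile"] * n_mobile,
        mobile="mobile",
    )


def _rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    th = np.deg2rad(angle_deg)
    k = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + np.sin(th) * k + (1 - np.cos(th)) * (k @ k)


def gen_domain_ensemble(
    scaffold: DomainScaffold,
    rotation_angles: Sequence[float],
    tilt_angles: Sequence[float],
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> PlantedEnsemble:
    """Rigid rotation + tilt of the mobile domain, one frame per angle pair.

    Each frame rotates the mobile-domain atoms about two fixed orthogonal axes
    (z then x) through the mobile-domain centroid (the hinge), then adds
    isotropic Gaussian noise of ``noise_sd`` Angstrom to every atom.  The
    returned ground truth contains the two planted circular-arc displacement
    directions (the small-angle limits of the two motions) on the mobile
    subset.
    """
    rotation_angles = np.asarray(rotation_angles, dtype=float)
    tilt_angles = np.asarray(tilt_angles, dtype=float)
    if rotation_angles.size == 0 or tilt_angles.size == 0:
        raise ValueError("angle lists must be non-empty")
    if rotation_angles.size != tilt_angles.size:
        raise ValueError("rotation and tilt angle lists must have equal length")

    rng = np.random.default_rng(seed)
    axes = np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0]])
    mob = scaffold.mobile_mask
    hinge = scaffold.coords[mob].mean(axis=0)

    frames = []
    for rot, tilt in zip(rotation_angles, tilt_angles):
        frame = scaffold.coords.copy()
        if rot != 0.0 or tilt != 0.0:
            r = _rotation_matrix(axes[1], tilt) @ _rotation_matrix(axes[0], rot)
            frame[mob] = (frame[mob] - hinge) @ r.T + hinge
        if noise_sd > 0:
            frame = frame + rng.normal(scale=noise_sd, size=frame.shape)
        frames.append(frame)

    res_ids = [str(i + 1) for i in range(len(scaffold.coords))]
    ensemble = StructureEnsemble(
        res_ids=res_ids,
        coords=np.stack(frames),
        labels=[f"frame{k}" for k in range(len(frames))],
        domains={r: l for r, l in zip(res_ids, scaffold.domain_labels)},
    )

    rel = scaffold.coords[mob] - hinge
    dirs = []
    for ax in axes:
        d = np.cross(np.broadcast_to(ax, rel.shape), rel).ravel()
        dirs.append(d / np.linalg.norm(d))
    return PlantedEnsemble(
        ensemble=ensemble,
        mode_directions=np.stack(dirs),
        hinge=hinge,
        axes=axes,
    )


# ---------------------------------------------------------------------------
# biased Langevin sampling
# ---------------------------------------------------------------------------

def _bias_energy_grad(x, center, k, dim):
    if dim == 1:
        return 0.5 * k * (x - center) ** 2, k * (x - center)
    d = np.asarray(x, dtype=float).copy()
    d[1:] = 0.0
    d[0] -= center
    g = k * d
    return 0.5 * k * d[0] ** 2, g


def sample_biased(
    potential: AnalyticPotential,
    bias: tuple[float, float] | None,
    kT: float = 1.0,
    n_steps: int = 100_000,
    dt: float = 5e-3,
    friction: float = 1.0,
    x0=None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Overdamped Langevin samples of U + harmonic bias.

    ``bias`` is ``(pm, km)`` acting on the first coordinate, or None for
    unbiased dynamics.  The integrator is the Leimkuhler-Matthews overdamped
    step (Euler drift with the average of consecutive noise increments),
    whose stationary distribution is exact for harmonic energies and accurate
    to O(dt^2) otherwise.  The first 10% of steps are discarded as burn-in.
    Returns the post-burn-in positions, shape ``(n_kept,)`` for 1D potentials
    or ``(n_kept, 2)`` for 2D.  Raises RuntimeError with the step index on
    trajectory divergence (dt too large).
    """
    if bias is not None:
        pm, km = float(bias[0]), float(bias[1])
        if km < 0:
            raise ValueError("bias spring constant must be >= 0")
    else:
        pm, km = 0.0, 0.0
    if n_steps < 10:
        raise ValueError("n_steps too small for burn-in")
    if rng is None:
        rng = np.random.default_rng(seed)

    dim = potential.dim
    if x0 is None:
        x = 0.0 if dim == 1 else np.zeros(dim)
    else:
        x = float(x0) if dim == 1 else np.array(x0, dtype=float)

    sigma = np.sqrt(2.0 * kT * dt / friction)
    mob = dt / friction
    burn = int(BURN_IN_FRACTION * n_steps)
    out = np.empty(n_steps - burn) if dim == 1 else np.empty((n_steps - burn, dim))

    prev = rng.standard_normal() if dim == 1 else rng.standard_normal(dim)
    block = 10_000
    step = 0
    # overflow during a diverging trajectory is expected right before the
    # explicit failure below; silence the intermediate warnings only
    with np.errstate(over="ignore", invalid="ignore"):
        while step < n_steps:
            nblk = min(block, n_steps - step)
            noise = rng.standard_normal(nblk if dim == 1 else (nblk, dim))
            for i in range(nblk):
                g = potential.gradient(x)
                if dim == 1:
                    g = float(g) + km * (x - pm)
                    x = x - mob * g + 0.5 * sigma * (prev + noise[i])
                else:
                    g = np.asarray(g, dtype=float).copy()
                    g[0] += km * (x[0] - pm)
                    x = x - mob * g + 0.5 * sigma * (prev + noise[i])
                prev = noise[i]
                if step >= burn:
                    out[step - burn] = x
                step += 1
            probe = x if dim == 1 else x[0]
            if not np.all(np.isfinite(np.atleast_1d(x))) or abs(probe) > 1e8:
                raise RuntimeError(
                    f"trajectory diverged by step {step} (dt={dt} too large?)"
                )
    return out


# ---------------------------------------------------------------------------
# two-state telegraph traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TelegraphSpec:
    """Parameters of a two-state telegraph single-molecule trace."""

    k_u2r: float = 6.6          # s^-1, unwinding -> rezipping
    k_r2u: float = 7.0          # s^-1, rezipping -> unwinding
    v_unwind: float = 50.0      # bp/s
    v_rezip: float = -50.0      # bp/s
    E_unwind: float = 0.66
    E_rezip: float = 0.29
    gamma_true: float = 0.78
    dt: float = 1.0 / 267.0     # s
    duration: float = 60.0      # s
    position_noise_sd: float = 0.0    # bp
    intensity_noise_sd: float = 0.0   # fraction of the intensity scale
    intensity_scale: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_u2r <= 0 or self.k_r2u <= 0:
            raise ValueError("rates must be positive")
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")
        for e in (self.E_unwind, self.E_rezip):
            if not 0.0 <= e <= 1.0:
                raise ValueError("efficiencies must lie in [0, 1]")
        if self.gamma_true <= 0:
            raise ValueError("gamma must be positive")


def gen_two_state_trace(spec: TelegraphSpec) -> SMTrace:
    """Event-wise two-state Markov trace discretized at ``spec.dt``.

    Dwells are drawn exactly from the exponential laws, then the continuous
    path is sampled: the position integrates the state velocity, and donor /
    acceptor intensities satisfy ``E = 1/(1 + gamma * ID/IA)`` in expectation.
    The exact state path and switch times are stored as ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    rates = {UNWINDING: spec.k_u2r, REZIPPING: spec.k_r2u}
    vels = {UNWINDING: spec.v_unwind, REZIPPING: spec.v_rezip}
    effs = {UNWINDING: spec.E_unwind, REZIPPING: spec.E_rezip}

    # exact exponential dwells, then discretization (avoids dwell bias)
    switch_times = [0.0]
    states = [UNWINDING]
    t = 0.0
    while t < spec.duration:
        t += rng.exponential(1.0 / rates[states[-1]])
        switch_times.append(min(t, spec.duration))
        states.append(REZIPPING if states[-1] == UNWINDING else UNWINDING)
    switch_times = np.asarray(switch_times)

    n = int(np.floor(spec.duration / spec.dt))
    time = np.arange(n) * spec.dt
    seg = np.searchsorted(switch_times, time, side="right") - 1
    state_per_sample = np.array([states[s] for s in seg], dtype=object)

    # exact integrated position at the segment starts
    seg_v = np.array([vels[s] for s in states[:-1]])
    seg_dur = np.diff(switch_times)
    pos_at_switch = np.concatenate([[0.0], np.cumsum(seg_v * seg_dur)])
    position = pos_at_switch[seg] + seg_v[np.minimum(seg, len(seg_v) - 1)] * (
        time - switch_times[seg]
    )
    if spec.position_noise_sd > 0:
        position = position + rng.normal(scale=spec.position_noise_sd, size=n)

    e_state = np.array([effs[s] for s in state_per_sample])
    acceptor = spec.intensity_scale * e_state
    donor = spec.intensity_scale * (1.0 - e_state) / spec.gamma_true
    if spec.intensity_noise_sd > 0:
        s = spec.intensity_noise_sd * spec.intensity_scale
        acceptor = acceptor + rng.normal(scale=s, size=n)
        donor = donor + rng.normal(scale=s, size=n)
    acceptor = np.clip(acceptor, 0.0, None)
    donor = np.clip(donor, 0.0, None)

    return SMTrace(
        time=time,
        position=position,
        donor=donor,
        acceptor=acceptor,
        sampling_rate=1.0 / spec.dt,
        true_states=state_per_sample,
        true_switch_times=switch_times[1:-1],  # interior switches only
    )


# ---------------------------------------------------------------------------
# photobleaching events
# ---------------------------------------------------------------------------

def gen_photobleach_events(
    n_events: int,
    gamma_true: float = 0.78,
    donor_step: float = 100.0,
    donor_base: float = 50.0,
    acceptor_base: float | None = None,
    noise_sd: float = 0.0,
    n_points: int = 200,
    dt: float = 0.01,
    seed: int | None = None,
) -> list[BleachEvent]:
    """Donor/acceptor traces with one acceptor-bleach step each.

    At the bleach the acceptor drops by ``gamma_true * donor_step`` while the
    donor rises by ``donor_step`` (in expectation under Gaussian noise of
    ``noise_sd`` intensity units).  Bleach times are recorded as ground truth.
    """
    if n_events < 1:
        raise ValueError("need at least one event")
    rng = np.random.default_rng(seed)
    if acceptor_base is None:
        acceptor_base = 1.5 * gamma_true * donor_step + 10.0
    events = []
    for _ in range(n_events):
        bleach_idx = int(rng.integers(n_points // 4, 3 * n_points // 4))
        time = np.arange(n_points) * dt
        donor = np.full(n_points, donor_base)
        acceptor = np.full(n_points, acceptor_base)
        donor[bleach_idx:] += donor_step
        acceptor[bleach_idx:] -= gamma_true * donor_step
        if noise_sd > 0:
            donor = donor + rng.normal(scale=noise_sd, size=n_points)
            acceptor = acceptor + rng.normal(scale=noise_sd, size=n_points)
        donor = np.clip(donor, 0.0, None)
        acceptor = np.clip(acceptor, 0.0, None)
        # bleach happens between samples bleach_idx-1 and bleach_idx
        bleach_time = float((bleach_idx - 0.5) * dt)
        events.append(
            BleachEvent(time=time, donor=donor, acceptor=acceptor,
                        bleach_time=bleach_time)
        )
    return events


# ---------------------------------------------------------------------------
# dye trajectories
# ---------------------------------------------------------------------------

def _uniform_sphere(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _planar_dipoles(kappa2: float, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Dipole pair perpendicular to the x-axis separation with the requested
    orientation factor: both in the y-z plane, angle phi with cos^2 phi = k2."""
    cos_phi = float(np.sqrt(np.clip(kappa2, 0.0, 1.0)))
    sin_phi = float(np.sqrt(1.0 - cos_phi**2))
    d = np.tile([0.0, 1.0, 0.0], (n, 1))
    a = np.tile([0.0, cos_phi, sin_phi], (n, 1))
    return d, a


def gen_dye_trajectory(
    R_mean: float = 51.0,
    R_sd: float = 0.0,
    orientation_model: str = "isotropic",
    n_frames: int = 1000,
    seed: int | None = None,
    dt: float = 1.0,
    E_targets: Sequence[float] | None = None,
    weights: Sequence[float] | None = None,
    R0_iso: float = 51.0,
    kappa2_fixed: float = 2.0 / 3.0,
) -> DyeTrajectory:
    """Dye dipole + separation trajectories with controlled statistics.

    Modes: ``"isotropic"`` draws both dipoles (and the separation direction)
    uniformly on the sphere; ``"fixed"`` repeats one geometry whose
    orientation factor equals ``kappa2_fixed``; ``"two-conformer"`` mixes two
    populations placed (at kappa^2 = 2/3) so the efficiency targets
    ``E_targets`` are hit in expectation, with mixture ``weights``.
    """
    if R_mean <= 0:
        raise ValueError("R_mean must be positive")
    rng = np.random.default_rng(seed)

    if orientation_model == "fixed":
        d, a = _planar_dipoles(kappa2_fixed, n_frames)
        sep = np.tile([R_mean, 0.0, 0.0], (n_frames, 1))
        return DyeTrajectory(d, a, sep, dt=dt)

    if orientation_model == "isotropic":
        d = _uniform_sphere(rng, n_frames)
        a = _uniform_sphere(rng, n_frames)
        rhat = _uniform_sphere(rng, n_frames)
        radii = np.clip(rng.normal(R_mean, R_sd, size=n_frames), 1.0, None)
        return DyeTrajectory(d, a, rhat * radii[:, None], dt=dt)

    if orientation_model == "two-conformer":
        if E_targets is None or len(E_targets) != 2:
            raise ValueError("two-conformer mode needs two E_targets")
        w = np.asarray(weights if weights is not None else (0.5, 0.5), dtype=float)
        w = w / w.sum()
        radii_pop = [
            R0_iso * ((1.0 - e) / e) ** (1.0 / 6.0) for e in E_targets
        ]
        pop = rng.choice(2, size=n_frames, p=w)
        d, a = _planar_dipoles(2.0 / 3.0, n_frames)
        radii = np.asarray([radii_pop[p] for p in pop])
        if R_sd > 0:
            radii = np.clip(radii + rng.normal(scale=R_sd, size=n_frames), 1.0, None)
        sep = np.zeros((n_frames, 3))
        sep[:, 0] = radii
        return DyeTrajectory(d, a, sep, dt=dt)

    raise ValueError(f"unknown orientation model {orientation_model!r}")
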