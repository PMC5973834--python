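"""Weighted-histogram reconstruction of unbiased free-energy surfaces.

Self-consistent histogram WHAM for 1D profiles, sample-wise reweighting for
2D surfaces whose bias acts on the first coordinate only, and Monte-Carlo
bootstrap standard errors.  Energies are handled in kT internally; a declared
temperature converts to kcal/mol on output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .hrex import WindowSamples

__all__ = [
    "PMFGrid",
    "histogram_windows",
    "solve_wham",
    "bootstrap_error",
    "pmf_2d",
    "KCAL_PER_KT_310K",
]

# k_B * 310 K in kcal/mol
KCAL_PER_KT_310K = 0.0019872041 * 310.0


@dataclass
class PMFGrid:
    """A free-energy surface on a regular 1D or 2D grid.

    ``values`` holds G per bin in ``unit`` (minimum over occupied bins = 0),
    ``errors`` the bootstrap SE (NaN where never computed), ``counts`` the
    total occupancy and ``mask`` flags empty bins (True = empty).
    """

    edges: tuple                  # (edges_x,) or (edges_x, edges_y)
    values: np.ndarray
    counts: np.ndarray
    mask: np.ndarray
    errors: np.ndarray | None = None
    unit: str = "kT"
    converged: bool = True
    n_iter: int = 0
    residual: float = 0.0
    shifts: np.ndarray | None = field(default=None, repr=False)  # f_m in kT

    def __post_init__(self) -> None:
        occupied = ~self.mask
        if occupied.any():
            mn = np.nanmin(self.values[occupied])
            if abs(mn) > 1e-6:
                raise ValueError("PMF must be anchored at min = 0")
        if self.errors is not None and np.any(self.errors[occupied] < 0):
            raise ValueError("negative standard error")

    @property
    def centers(self) -> tuple:
        return tuple(0.5 * (e[:-1] + e[1:]) for e in self.edges)

    def in_unit(self, unit: str, kcal_per_kt: float = KCAL_PER_KT_310K) -> "PMFGrid":
        """Return a converted copy ('kT' or 'kcal/mol')."""
        if unit == self.unit:
            return self
        factor = kcal_per_kt if unit == "kcal/mol" else 1.0 / kcal_per_kt
        return PMFGrid(
            edges=self.edges,
            values=self.values * factor,
            counts=self.counts,
            mask=self.mask,
            errors=None if self.errors is None else self.errors * factor,
            unit=unit,
            converged=self.converged,
            n_iter=self.n_iter,
            residual=self.residual,
            shifts=self.shifts,
        )


def histogram_windows(
    samples: WindowSamples,
    edges: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window histograms of the biased coordinate.

    Bins are half-open ``[e_i, e_{i+1})`` except the last, which is closed on
    the right (numpy convention).  Returns ``(counts (M, B), n_out_of_range)``;
    out-of-range samples are excluded from the bins but counted.
    """
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    counts = np.zeros((samples.n_windows, edges.size - 1))
    out = np.zeros(samples.n_windows, dtype=int)
    for m in range(samples.n_windows):
        xi = samples.coordinate(m)
        counts[m], _ = np.histogram(xi, bins=edges)
        out[m] = xi.size - int(counts[m].sum())
    if counts.sum() == 0:
        raise ValueError("all samples fall outside the bin range")
    return counts, out


def _bias_matrix(centers_bins, centers_w, springs) -> np.ndarray:
    """U_m(b) for every window m and bin center b, in the sampler's energy unit."""
    return 0.5 * springs[:, None] * (centers_bins[None, :] - centers_w[:, None]) ** 2


def solve_wham(
    counts: np.ndarray,
    biases: Sequence[tuple],
    kT: float = 1.0,
    edges: np.ndarray | None = None,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    f_init: np.ndarray | None = None,
    bias_matrix: np.ndarray | None = None,
) -> PMFGrid:
    """Standard self-consistent WHAM on per-window histograms.

    ``biases`` is a sequence of ``(p_m, k_m)``.  Iterates
    ``P(b) = sum_m n_m(b) / sum_m N_m exp(-(U_m(b) - f_m)/kT)`` and
    ``f_m = -kT ln sum_b P(b) exp(-U_m(b)/kT)`` until ``max |df_m| < tol``
    (tol in kT).  G = -kT ln P, anchored so the occupied minimum is 0.
    ``bias_matrix`` (M, B) overrides the harmonic form with arbitrary window
    energies U_m(b) in the sampler's energy unit.
    """
    counts = np.asarray(counts, dtype=float)
    M, B = counts.shape
    if len(biases) != M:
        raise ValueError("one (center, spring) pair per window required")
    if edges is None:
        raise ValueError("bin edges are required")
    edges = np.asarray(edges, dtype=float)
    centers_bins = 0.5 * (edges[:-1] + edges[1:])
    centers_w = np.asarray([b[0] for b in biases], dtype=float)
    springs = np.asarray([b[1] for b in biases], dtype=float)

    n_m = counts.sum(axis=1)                       # samples per window
    n_b = counts.sum(axis=0)                       # samples per bin
    occupied = n_b > 0
    if not occupied.any():
        raise ValueError("no occupied bins")
    # each occupied bin must be covered by at least one window's histogram
    if bias_matrix is not None:
        u = np.asarray(bias_matrix, dtype=float) / kT
        if u.shape != (M, B):
            raise ValueError("bias_matrix must have shape (n_windows, n_bins)")
    else:
        u = _bias_matrix(centers_bins, centers_w, springs) / kT   # dimensionless

    f = np.zeros(M) if f_init is None else np.asarray(f_init, dtype=float).copy()
    width = np.diff(edges)
    converged = False
    it = 0
    resid = np.inf
    for it in range(1, int(max_iter) + 1):
        denom = np.einsum("m,mb->b", n_m, np.exp(-(u - f[:, None])))
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(occupied, n_b / denom, 0.0)
        z = (p[None, :] * np.exp(-u)).sum(axis=1)
        f_new = -np.log(z)
        f_new -= f_new[0]                          # gauge fix
        resid = float(np.max(np.abs(f_new - f)))
        f = f_new
        if resid < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"WHAM did not converge in {max_iter} iterations (residual {resid:.3g} kT)"
        )
    _check_connected(occupied)

    p_norm = p / np.sum(p * width)
    g = np.full(B, np.nan)
    with np.errstate(divide="ignore"):
        g[occupied] = -kT * np.log(p_norm[occupied])
    g -= np.nanmin(g[occupied])
    return PMFGrid(
        edges=(edges,),
        values=g,
        counts=n_b,
        mask=~occupied,
        unit="kT",
        converged=converged,
        n_iter=it,
        residual=resid,
        shifts=f * kT,
    )


def _check_connected(occupied: np.ndarray) -> None:
    """Warn when the occupied support splits into islands (offsets undefined)."""
    occ = np.asarray(occupied).ravel()
    runs = np.flatnonzero(np.diff(occ.astype(int)) == 1).size + int(occ[0])
    if runs > 1:
        warnings.warn(
            "histogram support is disconnected; PMF offsets between islands "
            "are undefined"
        )


def bootstrap_error(
    samples: WindowSamples,
    edges: np.ndarray,
    n_trials: int = 10,
    seed: int | None = None,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    rng: np.random.Generator | None = None,
) -> PMFGrid:
    """WHAM with Monte-Carlo bootstrap SE per bin.

    Each trial resamples every window's samples with replacement, reruns the
    solver, re-anchors the trial's occupied minimum to 0, and the SE is the
    standard deviation over trials.  Returns the full-sample PMF with
    ``errors`` filled in.  ``rng`` (anything with an ``integers`` method)
    overrides ``seed``.
    """
    if n_trials < 2:
        raise ValueError("need at least 2 bootstrap trials")
    for m in range(samples.n_windows):
        if samples.coordinate(m).size < 2:
            raise ValueError(f"window {m} has fewer than 2 samples")
    if rng is None:
        rng = np.random.default_rng(seed)
    biases = list(zip(samples.centers, samples.springs))

    counts, _ = histogram_windows(samples, edges)
    pmf = solve_wham(counts, biases, kT=samples.kT, edges=edges,
                     tol=tol, max_iter=max_iter)

    trials = np.full((n_trials, counts.shape[1]), np.nan)
    for t in range(n_trials):
        boot_counts = np.zeros_like(counts)
        for m in range(samples.n_windows):
            xi = samples.coordinate(m)
            res = xi[rng.integers(0, xi.size, size=xi.size)]
            boot_counts[m], _ = np.histogram(res, bins=edges)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            trial = solve_wham(boot_counts, biases, kT=samples.kT, edges=edges,
                               tol=tol, max_iter=max_iter,
                               f_init=(pmf.shifts / samples.kT))
        trials[t] = trial.values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        se = np.nanstd(trials, axis=0, ddof=1)
    se = np.where(pmf.mask, np.nan, se)
    pmf.errors = np.abs(se)
    return pmf


def pmf_2d(
    samples: WindowSamples,
    edges_x: np.ndarray,
    edges_y: np.ndarray,
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> PMFGrid:
    """2D PMF from windows biased along the first coordinate only.

    Window shifts f_m come from 1D WHAM on the biased coordinate; every sample
    then carries the binless weight ``w = 1 / sum_m N_m exp(-(U_m(x1) - f_m)/kT)``
    which is accumulated in 2D bins (the bias is independent of coordinate 2).
    """
    sample0 = np.asarray(samples.samples[0])
    if sample0.ndim != 2 or sample0.shape[1] != 2:
        raise ValueError("2D PMF needs a second coordinate recorded per sample")
    edges_x = np.asarray(edges_x, dtype=float)
    edges_y = np.asarray(edges_y, dtype=float)
    kT = samples.kT

    counts, _ = histogram_windows(samples, edges_x)
    biases = list(zip(samples.centers, samples.springs))
    pmf1 = solve_wham(counts, biases, kT=kT, edges=edges_x,
                      tol=tol, max_iter=max_iter)
    f = pmf1.shifts / kT

    n_m = np.array([samples.coordinate(m).size for m in range(samples.n_windows)],
                   dtype=float)
    centers_w = samples.centers
    springs = samples.springs

    weights_grid = np.zeros((edges_x.size - 1, edges_y.size - 1))
    count_grid = np.zeros_like(weights_grid)
    for m in range(samples.n_windows):
        s = np.asarray(samples.samples[m], dtype=float)
        x1, x2 = s[:, 0], s[:, 1]
        u = 0.5 * springs[None, :] * (x1[:, None] - centers_w[None, :]) ** 2 / kT
        denom = (n_m[None, :] * np.exp(-(u - f[None, :]))).sum(axis=1)
        w = 1.0 / denom
        h_w, _, _ = np.histogram2d(x1, x2, bins=(edges_x, edges_y), weights=w)
        h_c, _, _ = np.histogram2d(x1, x2, bins=(edges_x, edges_y))
        weights_grid += h_w
        count_grid += h_c

    occupied = count_grid > 0
    g = np.full(weights_grid.shape, np.nan)
    with np.errstate(divide="ignore"):
        g[occupied] = -kT * np.log(weights_grid[occupied])
    g -= np.nanmin(g[occupied])
    return PMFGrid(
        edges=(edges_x, edges_y),
        values=g,
        counts=count_grid,
        mask=~occupied,
        unit="kT",
        converged=pmf1.converged,
        n_iter=pmf1.n_iter,
        residual=pmf1.residual,
        shifts=pmf1.shifts,
    )
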