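"""Lowest free-energy path extraction on a 2D PMF grid.

The path minimizes the maximum free energy encountered (minimax / bottleneck
objective) over 8-connected grid moves; ties are broken by cumulative energy,
then by path length.  The raw grid path is smoothed with a parametric spline
and resampled into uniformly spaced images, and the free-energy profile is
reported against the progress variable alpha (the affine rescaling of the
first coordinate between the endpoints).
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator, splev, splprep

from .wham import PMFGrid

__all__ = [
    "Path",
    "find_min_path",
    "smooth_and_resample",
    "alpha_profile",
]

_MOVES = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class Path:
    """An ordered chain of images across a 2D free-energy surface."""

    images: np.ndarray          # (n, 2) coordinates
    energies: np.ndarray        # (n,) interpolated G
    alpha: np.ndarray           # (n,) progress variable
    bottleneck_index: int
    barrier: float              # max image energy - start energy
    backtracks: bool = False    # True when alpha is non-monotone

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if not (len(self.images) == len(self.energies) == len(self.alpha)):
            raise ValueError("per-image arrays differ in length")

    def __len__(self) -> int:
        return len(self.images)


def _grid_values(pmf: PMFGrid) -> np.ndarray:
    if len(pmf.edges) != 2:
        raise ValueError("a 2D PMF is required")
    return pmf.values


def find_min_path(
    pmf: PMFGrid,
    start: tuple[int, int],
    end: tuple[int, int],
) -> list[tuple[int, int]]:
    """Minimax (bottleneck) path between two occupied bins.

    Dijkstra-style label setting with the lexicographic key
    ``(bottleneck energy, cumulative energy, length)``; masked bins are
    impassable.  Returns the chain of ``(ix, iy)`` bins from start to end.
    """
    g = _grid_values(pmf)
    mask = pmf.mask
    nx, ny = g.shape
    start, end = tuple(start), tuple(end)
    for p in (start, end):
        if not (0 <= p[0] < nx and 0 <= p[1] < ny):
            raise ValueError(f"bin {p} outside the grid")
        if mask[p]:
            raise ValueError(f"bin {p} is empty (masked)")

    best: dict = {}
    prev: dict = {}
    k0 = (float(g[start]), float(g[start]), 1)
    heap = [(k0, start)]
    best[start] = k0
    while heap:
        key, cell = heapq.heappop(heap)
        if best.get(cell, None) != key:
            continue
        if cell == end:
            break
        bott, cum, length = key
        for dx, dy in _MOVES:
            nxt = (cell[0] + dx, cell[1] + dy)
            if not (0 <= nxt[0] < nx and 0 <= nxt[1] < ny) or mask[nxt]:
                continue
            e = float(g[nxt])
            cand = (max(bott, e), cum + e, length + 1)
            if nxt not in best or cand < best[nxt]:
                best[nxt] = cand
                prev[nxt] = cell
                heapq.heappush(heap, (cand, nxt))
    if end not in best:
        raise ValueError("start and end bins are disconnected")

    chain = [end]
    while chain[-1] != start:
        chain.append(prev[chain[-1]])
    return chain[::-1]


def _interpolator(pmf: PMFGrid) -> RegularGridInterpolator:
    cx, cy = pmf.centers
    vals = pmf.values.copy()
    if pmf.mask.any():
        fill = np.nanmax(vals[~pmf.mask]) + 10.0
        vals[pmf.mask] = fill
    return RegularGridInterpolator(
        (cx, cy), vals, method="linear", bounds_error=False, fill_value=None
    )


def _resample_uniform(pts: np.ndarray, n_images: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    if arc[-1] == 0:
        return np.tile(pts[0], (n_images, 1))
    targets = np.linspace(0.0, arc[-1], n_images)
    out = np.empty((n_images, 2))
    for d in range(2):
        out[:, d] = np.interp(targets, arc, pts[:, d])
    return out


def smooth_and_resample(
    raw_path: Sequence[tuple[int, int]],
    pmf: PMFGrid,
    n_images: int = 120,
    smoothing: float | None = None,
) -> Path:
    """Spline-smooth a raw grid path and resample it at uniform arc length.

    Per-image energies come from bilinear PMF interpolation.  If smoothing
    would raise the path maximum above the raw bottleneck by more than one
    bootstrap SE at the bottleneck bin (or 1e-9 without errors), the
    smoothing factor is halved; the unsmoothed polyline is the final
    fallback, whose bilinear maximum cannot exceed the raw bottleneck.
    """
    if len(raw_path) < 2:
        raise ValueError("raw path needs at least 2 points")
    if n_images < 2:
        raise ValueError("need at least 2 images")
    g = _grid_values(pmf)
    cx, cy = pmf.centers
    pts = np.array([[cx[i], cy[j]] for i, j in raw_path], dtype=float)
    raw_bott_bin = max(raw_path, key=lambda b: g[b])
    raw_bottleneck = float(g[raw_bott_bin])
    allowance = 1e-9
    if pmf.errors is not None and np.isfinite(pmf.errors[raw_bott_bin]):
        allowance = max(allowance, float(pmf.errors[raw_bott_bin]))

    interp = _interpolator(pmf)

    def _energies(images: np.ndarray) -> np.ndarray:
        return np.asarray(interp(images), dtype=float)

    m = len(pts)
    s = smoothing if smoothing is not None else max(m - np.sqrt(2 * m), 0.0)
    images = None
    for _ in range(40):
        images = _try_spline(pts, s, n_images)
        if images is None:
            break
        if _energies(images).max() <= raw_bottleneck + allowance:
            break
        s *= 0.5
        if s < 1e-12:
            images = None
            break
    if images is None:  # polyline fallback: piecewise linear through raw points
        images = _resample_uniform(pts, n_images)
    # pin the endpoints exactly
    images[0], images[-1] = pts[0], pts[-1]

    energies = _energies(images)
    alpha = _alpha(images)
    bott = int(np.argmax(energies))
    backtracks = bool(np.any(np.diff(alpha) < -1e-12))
    if backtracks:
        warnings.warn("alpha backtracks along the smoothed path")
    return Path(
        images=images,
        energies=energies,
        alpha=alpha,
        bottleneck_index=bott,
        barrier=float(energies.max() - energies[0]),
        backtracks=backtracks,
    )


def _try_spline(pts: np.ndarray, s: float, n_images: int) -> np.ndarray | None:
    uniq = np.any(np.abs(np.diff(pts, axis=0)) > 1e-12, axis=1)
    keep = np.concatenate([[True], uniq])
    p = pts[keep]
    if len(p) < 2:
        return None
    k = min(3, len(p) - 1)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tck, _ = splprep([p[:, 0], p[:, 1]], s=s, k=k)
        dense = np.column_stack(splev(np.linspace(0, 1, max(40 * n_images, 400)), tck))
    except Exception:
        return None
    if not np.all(np.isfinite(dense)):
        return None
    return _resample_uniform(dense, n_images)


def _alpha(images: np.ndarray) -> np.ndarray:
    x0, x1 = images[0, 0], images[-1, 0]
    if abs(x1 - x0) < 1e-12:
        return np.full(len(images), np.nan)
    return (images[:, 0] - x0) / (x1 - x0)


def alpha_profile(path: Path) -> np.ndarray:
    """(alpha, G) table with G relative to the start image."""
    if np.any(~np.isfinite(path.alpha)):
        raise ValueError("endpoint first coordinates coincide; alpha undefined")
    return np.column_stack([path.alpha, path.energies - path.energies[0]])
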