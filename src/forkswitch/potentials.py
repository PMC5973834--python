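"""Analytic test potentials with known minima, saddles and barriers.

Energies are in units of kT unless stated otherwise.  These surfaces stand in
for the molecular energy landscape: every downstream free-energy estimator is
validated against their closed-form features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "AnalyticPotential",
    "flat",
    "harmonic",
    "double_well",
    "two_basin_2d",
]

_FD_STEP = 1e-6


@dataclass(frozen=True)
class AnalyticPotential:
    """An analytic energy surface U(x) in kT with declared features.

    Parameters
    ----------
    dim : int
        Dimensionality, 1 or 2.
    energy : callable
        Maps an array of shape ``(..., dim)`` (or scalar/1-d for ``dim == 1``)
        to energies in kT.
    label : str
        Human-readable name.
    minima : sequence of points
        Known local minima.
    saddle : point or None
        Known saddle (1D: barrier top).
    barrier : float or None
        Barrier height ``U(saddle) - U(minima[0])`` in kT.
    """

    dim: int
    energy: Callable[[np.ndarray], np.ndarray]
    label: str
    minima: tuple = ()
    saddle: object = None
    barrier: float | None = None
    _grad: Callable[[np.ndarray], np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.dim not in (1, 2):
            raise ValueError(f"dim must be 1 or 2, got {self.dim}")

    def __call__(self, x) -> np.ndarray:
        return self.energy(np.asarray(x, dtype=float))

    def gradient(self, x) -> np.ndarray:
        """dU/dx, analytic if supplied, else central finite differences."""
        x = np.asarray(x, dtype=float)
        if self._grad is not None:
            return self._grad(x)
        if self.dim == 1:
            return (self.energy(x + _FD_STEP) - self.energy(x - _FD_STEP)) / (2 * _FD_STEP)
        g = np.empty(x.shape, dtype=float)
        for k in range(self.dim):
            h = np.zeros(self.dim)
            h[k] = _FD_STEP
            g[..., k] = (self.energy(x + h) - self.energy(x - h)) / (2 * _FD_STEP)
        return g

    def check_stationary(self, tol: float = 1e-6) -> None:
        """Verify |grad U| < tol at every declared minimum and the saddle."""
        points = list(self.minima)
        if self.saddle is not None:
            points.append(self.saddle)
        for p in points:
            g = np.atleast_1d(self.gradient(np.asarray(p, dtype=float)))
            if np.max(np.abs(g)) >= tol:
                raise ValueError(
                    f"{self.label}: |grad U({p})| = {np.max(np.abs(g)):.3g} >= {tol}"
                )


def flat() -> AnalyticPotential:
    """U(x) = 0 everywhere."""
    return AnalyticPotential(
        dim=1,
        energy=lambda x: np.zeros_like(np.asarray(x, dtype=float)),
        label="flat",
        _grad=lambda x: np.zeros_like(np.asarray(x, dtype=float)),
    )


def harmonic(k: float = 1.0) -> AnalyticPotential:
    """U(x) = k x^2 / 2."""
    return AnalyticPotential(
        dim=1,
        energy=lambda x: 0.5 * k * np.square(x),
        label=f"harmonic(k={k})",
        minima=(0.0,),
        _grad=lambda x: k * np.asarray(x, dtype=float),
    )


def double_well() -> AnalyticPotential:
    """U(x) = (x^2 - 1)^2: minima at +-1, saddle at 0, barrier 1 kT."""
    return AnalyticPotential(
        dim=1,
        energy=lambda x: np.square(np.square(x) - 1.0),
        label="double_well",
        minima=(-1.0, 1.0),
        saddle=0.0,
        barrier=1.0,
        _grad=lambda x: 4.0 * np.asarray(x, dtype=float) * (np.square(x) - 1.0),
    )


def two_basin_2d(well_k: float = 2.0) -> AnalyticPotential:
    """U(x, y) = (x^2 - 1)^2 + well_k * y^2: basins at (+-1, 0), saddle (0, 0)."""

    def _u(p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        x, y = p[..., 0], p[..., 1]
        return np.square(np.square(x) - 1.0) + well_k * np.square(y)

    def _g(p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        x, y = p[..., 0], p[..., 1]
        g = np.empty(p.shape, dtype=float)
        g[..., 0] = 4.0 * x * (np.square(x) - 1.0)
        g[..., 1] = 2.0 * well_k * y
        return g

    return AnalyticPotential(
        dim=2,
        energy=_u,
        label=f"two_basin_2d(well_k={well_k})",
        minima=((-1.0, 0.0), (1.0, 0.0)),
        saddle=(0.0, 0.0),
        barrier=1.0,
        _grad=_g,
    )
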