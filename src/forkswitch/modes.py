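"""PCA of structural ensembles: covariance, eigenmodes, projections and
involvement coefficients of a conformational displacement."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .structures import StructureEnsemble

__all__ = [
    "ModeSet",
    "Projection",
    "covariance",
    "eigenmodes",
    "pca",
    "project",
    "involvement_coefficients",
]


@dataclass
class ModeSet:
    """Principal modes of a coordinate covariance matrix.

    ``mean`` is the 3n mean coordinate vector of the analysed atoms, ``modes``
    the unit eigenvectors as rows (descending eigenvalue), ``eigenvalues`` in
    square Angstrom.
    """

    mean: np.ndarray          # (3n,)
    modes: np.ndarray         # (n_modes, 3n), rows are unit vectors
    eigenvalues: np.ndarray   # (n_modes,), descending, >= 0
    subset_res_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.modes = np.atleast_2d(np.asarray(self.modes, dtype=float))
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        norms = np.linalg.norm(self.modes, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("modes must be unit vectors")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be non-increasing")
        if np.any(self.eigenvalues < -1e-10):
            raise ValueError("eigenvalues must be non-negative")

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]


@dataclass
class Projection:
    """Per-frame scalar coordinates (Angstrom) along selected modes."""

    values: np.ndarray        # (K, n_selected)
    mode_indices: tuple


def _flatten(ensemble: StructureEnsemble, subset: Sequence[str] | None):
    if subset is None:
        idx = np.arange(ensemble.n_atoms)
    else:
        idx = ensemble.atom_indices(subset)
        if len(idx) == 0:
            raise ValueError(f"subset {subset} selects no atoms")
    x = ensemble.coords[:, idx, :].reshape(ensemble.n_frames, -1)
    res_ids = [ensemble.res_ids[i] for i in idx]
    return x, res_ids


def covariance(ensemble: StructureEnsemble, subset: Sequence[str] | None = None):
    """Population covariance (divisor K) of the subset coordinates.

    Returns ``(sigma, mean, subset_res_ids)``; the ensemble is expected to be
    superposed already.
    """
    if ensemble.n_frames < 2:
        raise ValueError("need at least 2 frames")
    x, res_ids = _flatten(ensemble, subset)
    mu = x.mean(axis=0)
    d = x - mu
    sigma = (d.T @ d) / x.shape[0]
    return sigma, mu, res_ids


def eigenmodes(
    sigma: np.ndarray,
    n_modes: int | None = None,
    mean: np.ndarray | None = None,
    subset_res_ids: Sequence | None = None,
) -> ModeSet:
    """Top eigenpairs of a symmetric covariance matrix, descending eigenvalue.

    The sign of each eigenvector is fixed so its largest-magnitude component
    is positive, making projections reproducible across solvers.
    """
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(sigma, sigma.T, atol=1e-8 * max(1.0, np.abs(sigma).max())):
        raise ValueError("covariance must be symmetric")
    w, v = np.linalg.eigh(sigma)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    if n_modes is not None:
        w, v = w[:n_modes], v[:, :n_modes]
    modes = v.T.copy()
    for i in range(modes.shape[0]):
        j = np.argmax(np.abs(modes[i]))
        if modes[i, j] < 0:
            modes[i] = -modes[i]
    w = np.clip(w, 0.0, None)
    mean = np.zeros(sigma.shape[0]) if mean is None else np.asarray(mean, dtype=float)
    return ModeSet(
        mean=mean, modes=modes, eigenvalues=w,
        subset_res_ids=list(subset_res_ids or []),
    )


def pca(
    ensemble: StructureEnsemble,
    subset: Sequence[str] | None = None,
    n_modes: int | None = None,
) -> ModeSet:
    """Convenience: covariance + eigenmodes on a superposed ensemble."""
    sigma, mu, res_ids = covariance(ensemble, subset)
    return eigenmodes(sigma, n_modes=n_modes, mean=mu, subset_res_ids=res_ids)


def _as_flat_frames(frames, n_dof: int) -> np.ndarray:
    x = np.asarray(frames, dtype=float)
    if x.ndim == 3:          # (K, n, 3)
        x = x.reshape(x.shape[0], -1)
    elif x.ndim == 2 and x.shape[1] == 3 and x.size == n_dof:
        x = x.reshape(1, -1)  # single (n, 3) frame
    elif x.ndim == 1:
        x = x.reshape(1, -1)
    if x.shape[1] != n_dof:
        raise ValueError(f"frame has {x.shape[1]} dof, modes expect {n_dof}")
    return x


def project(
    frames,
    modes: ModeSet,
    mode_indices: Sequence[int] = (0, 1),
) -> Projection:
    """p_i = v_i . (r - <r>) for each frame and each selected mode."""
    x = _as_flat_frames(frames, modes.mean.shape[0])
    sel = np.asarray(mode_indices, dtype=int)
    vals = (x - modes.mean) @ modes.modes[sel].T
    return Projection(values=vals, mode_indices=tuple(int(i) for i in sel))


def involvement_coefficients(modes: ModeSet, start, end) -> np.ndarray:
    """eta_i = |v_i . dR| with dR the unit start->end displacement."""
    n_dof = modes.mean.shape[0]
    r0 = _as_flat_frames(start, n_dof)[0]
    r1 = _as_flat_frames(end, n_dof)[0]
    d = r1 - r0
    norm = np.linalg.norm(d)
    if norm < 1e-12:
        raise ValueError("zero displacement between start and end frames")
    return np.abs(modes.modes @ (d / norm))
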