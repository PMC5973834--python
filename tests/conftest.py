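from __future__ import annotations

import numpy as np
import pytest

from forkswitch import synthetic_data as synth


def format_pdb_atom(serial, name, res_name, chain, res_seq, xyz, *,
                    altloc=" ", icode=" ", occupancy=1.0, element=None):
    """One fixed-width ATOM record."""
    if element is None:
        element = name.strip()[0]
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {name_field:<4s}{altloc}{res_name:>3s} {chain}"
        f"{res_seq:4d}{icode}   {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{occupancy:6.2f}{0.0:6.2f}          {element:>2s}"
    )


def write_pdb(path, lines):
    path.write_text("\n".join(lines + ["END"]) + "\n")


@pytest.fixture
def three_residue_pdb(tmp_path):
    """Three CA residues at (1,0,0), (2,0,0), (3,0,0)."""
    lines = [
        format_pdb_atom(1, "CA", "ALA", "A", 1, (1.0, 0.0, 0.0)),
        format_pdb_atom(2, "CA", "GLY", "A", 2, (2.0, 0.0, 0.0)),
        format_pdb_atom(3, "CA", "SER", "A", 3, (3.0, 0.0, 0.0)),
    ]
    p = tmp_path / "three.pdb"
    write_pdb(p, lines)
    return p


@pytest.fixture
def scaffold():
    return synth.demo_scaffold(n_static=30, n_mobile=20, seed=0)


@pytest.fixture
def planted_ensemble(scaffold):
    """20 frames with independent rotation/tilt angles, no noise, superposed
    by construction (static domain is never moved)."""
    rng = np.random.default_rng(42)
    return synth.gen_domain_ensemble(
        scaffold,
        rotation_angles=rng.uniform(-15, 15, size=20),
        tilt_angles=rng.uniform(-15, 15, size=20),
        noise_sd=0.0,
        seed=1,
    )


def subspace_angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    """Largest principal angle between the row spaces of a and b, degrees."""
    qa, _ = np.linalg.qr(np.atleast_2d(a).T)
    qb, _ = np.linalg.qr(np.atleast_2d(b).T)
    s = np.linalg.svd(qa.T @ qb, compute_uv=False)
    s = np.clip(s, -1.0, 1.0)
    return float(np.degrees(np.arccos(s.min())))


def block_se(x: np.ndarray, n_blocks: int = 20) -> float:
    """Autocorrelation-robust SE of the mean by block averaging."""
    x = np.asarray(x, dtype=float)
    m = len(x) // n_blocks
    means = x[: m * n_blocks].reshape(n_blocks, m).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_blocks))
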