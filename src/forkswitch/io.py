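"""Plain-text readers and writers for the pipeline's tabular formats.

All formats are TSV with ``#``-prefixed header comments; PDB output goes
through biotite.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .fret import DyeTrajectory
from .hrex import WindowSamples
from .structures import StructureEnsemble
from .traces import SMTrace
from .wham import PMFGrid

__all__ = [
    "write_trace_tsv", "read_trace_tsv",
    "write_window_samples_tsv", "read_window_samples_tsv",
    "write_dye_tsv", "read_dye_tsv",
    "write_pmf_tsv",
    "write_path_tsv",
    "write_ensemble_pdb",
]


def _write_tsv(df: pd.DataFrame, path, comments: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_trace_tsv(trace: SMTrace, path) -> None:
    df = pd.DataFrame({
        "time_s": trace.time,
        "position_bp": trace.position,
        "I_donor": trace.donor,
        "I_acceptor": trace.acceptor,
    })
    comments = [f"sampling_rate_hz={trace.sampling_rate}"]
    if trace.true_states is not None:
        df["true_state"] = trace.true_states
    _write_tsv(df, path, comments)


def read_trace_tsv(path) -> SMTrace:
    df = pd.read_csv(path, sep="\t", comment="#")
    return SMTrace(
        time=df["time_s"].to_numpy(),
        position=df["position_bp"].to_numpy(),
        donor=df["I_donor"].to_numpy(),
        acceptor=df["I_acceptor"].to_numpy(),
        true_states=(df["true_state"].to_numpy(dtype=object)
                     if "true_state" in df else None),
    )


def write_window_samples_tsv(samples: WindowSamples, path) -> None:
    rows = []
    for m in range(samples.n_windows):
        s = np.asarray(samples.samples[m])
        xi1 = s if s.ndim == 1 else s[:, 0]
        xi2 = np.full(len(xi1), np.nan) if s.ndim == 1 else s[:, 1]
        for a, b in zip(xi1, xi2):
            rows.append((m, samples.centers[m], samples.springs[m], a, b))
    df = pd.DataFrame(rows, columns=["window_id", "pm", "km", "sample", "sample2"])
    if df["sample2"].isna().all():
        df = df.drop(columns=["sample2"])
    _write_tsv(df, path, [f"kT={samples.kT}"])


def read_window_samples_tsv(path) -> WindowSamples:
    kT = 1.0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "kT=" in line:
                kT = float(line.split("kT=")[1])
            if not line.startswith("#"):
                break
    df = pd.read_csv(path, sep="\t", comment="#")
    centers, springs, arrays = [], [], []
    for wid, grp in df.groupby("window_id", sort=True):
        centers.append(grp["pm"].iloc[0])
        springs.append(grp["km"].iloc[0])
        if "sample2" in grp:
            arrays.append(grp[["sample", "sample2"]].to_numpy())
        else:
            arrays.append(grp["sample"].to_numpy())
    return WindowSamples(centers=np.array(centers), springs=np.array(springs),
                         kT=kT, samples=arrays)


def write_dye_tsv(traj: DyeTrajectory, path) -> None:
    df = pd.DataFrame({
        "frame": np.arange(len(traj)),
        "dDx": traj.donor_dipole[:, 0], "dDy": traj.donor_dipole[:, 1],
        "dDz": traj.donor_dipole[:, 2],
        "dAx": traj.acceptor_dipole[:, 0], "dAy": traj.acceptor_dipole[:, 1],
        "dAz": traj.acceptor_dipole[:, 2],
        "rx": traj.separation[:, 0], "ry": traj.separation[:, 1],
        "rz": traj.separation[:, 2],
    })
    _write_tsv(df, path, [f"dt_ns={traj.dt}"])


def read_dye_tsv(path) -> DyeTrajectory:
    dt = 1.0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "dt_ns=" in line:
                dt = float(line.split("dt_ns=")[1])
            if not line.startswith("#"):
                break
    df = pd.read_csv(path, sep="\t", comment="#")
    return DyeTrajectory(
        donor_dipole=df[["dDx", "dDy", "dDz"]].to_numpy(),
        acceptor_dipole=df[["dAx", "dAy", "dAz"]].to_numpy(),
        separation=df[["rx", "ry", "rz"]].to_numpy(),
        dt=dt,
    )


def write_pmf_tsv(pmf: PMFGrid, path) -> None:
    if len(pmf.edges) == 1:
        (cx,) = pmf.centers
        df = pd.DataFrame({
            "bin_center": cx,
            "G": pmf.values,
            "SE": pmf.errors if pmf.errors is not None else np.nan,
            "count": pmf.counts,
            "empty": pmf.mask.astype(int),
        })
    else:
        cx, cy = pmf.centers
        gx, gy = np.meshgrid(cx, cy, indexing="ij")
        df = pd.DataFrame({
            "bin_center_1": gx.ravel(),
            "bin_center_2": gy.ravel(),
            "G": pmf.values.ravel(),
            "SE": (pmf.errors.ravel() if pmf.errors is not None
                   else np.full(pmf.values.size, np.nan)),
            "count": pmf.counts.ravel(),
            "empty": pmf.mask.ravel().astype(int),
        })
    _write_tsv(df, path, [f"unit={pmf.unit}", f"converged={pmf.converged}"])


def write_path_tsv(path_obj, out) -> None:
    df = pd.DataFrame({
        "image": np.arange(len(path_obj)),
        "coord1": path_obj.images[:, 0],
        "coord2": path_obj.images[:, 1],
        "alpha": path_obj.alpha,
        "G": path_obj.energies,
    })
    _write_tsv(df, out, [f"barrier={path_obj.barrier}",
                         f"bottleneck_index={path_obj.bottleneck_index}"])


def write_ensemble_pdb(ensemble: StructureEnsemble, path) -> None:
    """Write every frame of an ensemble as a PDB model (CA-only)."""
    n = ensemble.n_atoms
    arrays = []
    for k in range(ensemble.n_frames):
        atoms = struc.AtomArray(n)
        atoms.coord = ensemble.coords[k]
        atoms.chain_id = np.array(["A"] * n)
        atoms.res_id = np.array(
            [int("".join(c for c in r if c.isdigit())) for r in ensemble.res_ids]
        )
        atoms.ins_code = np.array([""] * n)
        atoms.res_name = np.array(["ALA"] * n)
        atoms.atom_name = np.array(["CA"] * n)
        atoms.element = np.array(["C"] * n)
        atoms.hetero = np.array([False] * n)
        arrays.append(atoms)
    stack = struc.stack(arrays)
    f = pdb.PDBFile()
    f.set_structure(stack)
    f.write(str(path))


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
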