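"""C-alpha structure handling: PDB reading, homolog filtering, mapping onto a
query chain, ensemble building, Kabsch superposition and inter-domain metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

import biotite.structure as struc
import biotite.structure.io.pdb as pdb

__all__ = [
    "CalphaChain",
    "HomologHit",
    "MappedFrame",
    "StructureEnsemble",
    "read_calpha",
    "filter_homologs",
    "map_to_query",
    "build_ensemble",
    "superpose",
    "kabsch",
    "gap_size",
    "contact_coordinate",
    "alignment_from_fasta",
    "align_sequences",
    "load_domain_ranges",
    "domains_from_ranges",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CalphaChain:
    """One chain reduced to its C-alpha trace.

    ``res_ids`` are the source residue numbers (insertion codes appended, e.g.
    ``"100A"``), strictly increasing in sequence order.  ``extra_atoms`` holds
    optional named atoms keyed by ``(res_id, atom_name)``.
    """

    res_ids: list[str]
    res_names: list[str]
    coords: np.ndarray  # (N, 3) in Angstrom
    chain_id: str = ""
    extra_atoms: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (N, 3)")
        if len(self.res_ids) != len(self.coords):
            raise ValueError("res_ids and coords length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        numeric = [_res_num(r) for r in self.res_ids]
        if any(b <= a for a, b in zip(numeric, numeric[1:])):
            # equal numeric ids are allowed only via insertion codes
            for (a, ka), (b, kb) in zip(
                zip(numeric, self.res_ids), zip(numeric[1:], self.res_ids[1:])
            ):
                if b < a or (b == a and ka == kb):
                    raise ValueError("residue ids not strictly increasing")

    def __len__(self) -> int:
        return len(self.res_ids)

    def index_of(self, res_id: str | int) -> int:
        return self.res_ids.index(str(res_id))

    def select(self, res_ids: Iterable[str | int]) -> np.ndarray:
        """Coordinates of the given residues, in chain order."""
        wanted = {str(r) for r in res_ids}
        mask = np.array([r in wanted for r in self.res_ids], dtype=bool)
        if not mask.any():
            raise ValueError("no requested residues present in chain")
        return self.coords[mask]


def _res_num(res_id: str) -> int:
    s = str(res_id)
    tail = s.rstrip("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
    return int(tail)


@dataclass(frozen=True)
class HomologHit:
    """A sequence-search hit: identity in percent, coverage as a fraction."""

    subject_id: str
    identity: float
    coverage: float
    alignment: tuple = ()  # pairs of (query_res_id, subject_res_id)

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError("identity must be in [0, 100]")
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must be in [0, 1]")


@dataclass
class MappedFrame:
    """Homolog coordinates placed on the query residue index."""

    res_ids: list[str]           # full query index
    coords: np.ndarray           # (Nq, 3); rows with mask False are undefined
    mask: np.ndarray             # (Nq,) bool, True where a homolog Calpha landed
    label: str = ""


@dataclass
class StructureEnsemble:
    """Frames of C-alpha coordinates on a common query residue index."""

    res_ids: list[str]                 # common index, length n
    coords: np.ndarray                 # (K, n, 3)
    labels: list[str]
    domains: dict = field(default_factory=dict)  # res_id -> domain label

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (K, n, 3)")
        if self.coords.shape[1] != len(self.res_ids):
            raise ValueError("frame width does not match residue index")
        if self.coords.shape[1] < 3:
            raise ValueError("need at least 3 common residues")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def atom_indices(self, domain_labels: Sequence[str]) -> np.ndarray:
        wanted = set(domain_labels)
        idx = np.array(
            [i for i, r in enumerate(self.res_ids) if self.domains.get(r) in wanted],
            dtype=int,
        )
        return idx


# ---------------------------------------------------------------------------
# PDB input
# ---------------------------------------------------------------------------

def read_calpha(
    source: str | Path,
    chain_id: str | None = None,
    extra_atom_names: Sequence[str] = (),
) -> CalphaChain:
    """Read one chain's C-alpha trace from a PDB file.

    Altloc is resolved by keeping the highest-occupancy location (ties go to
    'A' by lexicographic order of the altloc id).  Residues without a C-alpha
    are dropped.  ``extra_atom_names`` (e.g. ``("OG1", "O2P")``) are attached
    to ``extra_atoms`` keyed by ``(res_id, atom_name)`` where present.
    """
    pdb_file = pdb.PDBFile.read(str(source))
    atoms = pdb_file.get_structure(model=1, altloc="occupancy")
    chains = sorted(set(atoms.chain_id))
    if chain_id is None:
        if len(chains) != 1:
            raise ValueError(f"chain_id required; file has chains {chains}")
        chain_id = chains[0]
    if chain_id not in chains:
        raise ValueError(f"chain {chain_id!r} not in {chains}")
    atoms = atoms[atoms.chain_id == chain_id]

    ca = atoms[atoms.atom_name == "CA"]
    # guard against calcium ions sharing the CA atom name
    ca = ca[np.isin(ca.element, ["C", ""])]
    if ca.array_length() == 0:
        raise ValueError(f"chain {chain_id!r} has no C-alpha atoms")

    res_ids, res_names, coords = [], [], []
    seen = set()
    for i in range(ca.array_length()):
        rid = f"{ca.res_id[i]}{ca.ins_code[i].strip()}"
        if rid in seen:  # residual altloc duplicates
            continue
        seen.add(rid)
        res_ids.append(rid)
        res_names.append(str(ca.res_name[i]))
        coords.append(ca.coord[i])

    extra: dict = {}
    if extra_atom_names:
        sel = atoms[np.isin(atoms.atom_name, list(extra_atom_names))]
        for i in range(sel.array_length()):
            rid = f"{sel.res_id[i]}{sel.ins_code[i].strip()}"
            extra[(rid, str(sel.atom_name[i]))] = np.array(sel.coord[i], dtype=float)

    return CalphaChain(
        res_ids=res_ids,
        res_names=res_names,
        coords=np.asarray(coords, dtype=float),
        chain_id=chain_id,
        extra_atoms=extra,
    )


# ---------------------------------------------------------------------------
# homolog filtering and mapping
# ---------------------------------------------------------------------------

def filter_homologs(
    hits: Sequence[HomologHit],
    min_identity: float = 40.0,
    min_coverage: float = 0.6,
) -> list[HomologHit]:
    """Keep hits with identity strictly above ``min_identity`` (percent) AND
    coverage strictly above ``min_coverage`` (fraction).  Order preserved."""
    return [h for h in hits if h.identity > min_identity and h.coverage > min_coverage]


def map_to_query(
    query: CalphaChain,
    homolog: CalphaChain,
    alignment: Sequence[tuple],
    label: str = "",
) -> MappedFrame:
    """Place homolog C-alpha coordinates onto the query residue index.

    ``alignment`` is a sequence of ``(query_res_id, homolog_res_id)`` pairs of
    one-to-one aligned positions.  Query positions that are unaligned, or whose
    aligned homolog residue has no C-alpha, are masked; gaps are never
    interpolated.
    """
    q_index = {r: i for i, r in enumerate(query.res_ids)}
    h_index = {r: i for i, r in enumerate(homolog.res_ids)}
    coords = np.zeros((len(query), 3), dtype=float)
    mask = np.zeros(len(query), dtype=bool)
    for q_res, h_res in alignment:
        q_res, h_res = str(q_res), str(h_res)
        if q_res not in q_index:
            raise KeyError(f"alignment references absent query residue {q_res!r}")
        if h_res not in h_index:
            raise KeyError(f"alignment references absent homolog residue {h_res!r}")
        qi = q_index[q_res]
        coords[qi] = homolog.coords[h_index[h_res]]
        mask[qi] = True
    return MappedFrame(
        res_ids=list(query.res_ids), coords=coords, mask=mask,
        label=label or homolog.chain_id,
    )


def build_ensemble(
    frames: Sequence[MappedFrame],
    domains: Mapping[str, str] | None = None,
) -> StructureEnsemble:
    """Restrict all frames to the intersection of their coverage masks."""
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    ref_ids = frames[0].res_ids
    for f in frames[1:]:
        if f.res_ids != ref_ids:
            raise ValueError("frames use different query indices")
    common = np.logical_and.reduce([f.mask for f in frames])
    if common.sum() < 3:
        raise ValueError("common residue index is (nearly) empty")
    res_ids = [r for r, keep in zip(ref_ids, common) if keep]
    coords = np.stack([f.coords[common] for f in frames])
    dom = {r: domains[r] for r in res_ids if domains and r in domains} if domains else {}
    return StructureEnsemble(
        res_ids=res_ids,
        coords=coords,
        labels=[f.label for f in frames],
        domains=dom,
    )


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid fit of ``mobile`` onto ``target``.

    Returns ``(R, t)`` such that ``mobile @ R.T + t`` minimises the RMSD to
    ``target``; R is a proper rotation (det +1), never a reflection.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.shape[0] < 3:
        raise ValueError("need matching point sets with >= 3 points")
    mu_m, mu_t = mobile.mean(axis=0), target.mean(axis=0)
    a, b = mobile - mu_m, target - mu_t
    if np.linalg.matrix_rank(a) < 2:
        raise ValueError("fit subset is degenerate (collinear points)")
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = mu_t - mu_m @ rot.T
    return rot, trans


def superpose(
    ensemble: StructureEnsemble,
    reference: int = 0,
    fit_domains: Sequence[str] = ("1A", "2A", "1B"),
) -> StructureEnsemble:
    """Rigidly fit every frame's ``fit_domains`` atoms onto the reference frame."""
    idx = ensemble.atom_indices(fit_domains)
    if len(idx) < 3:
        raise ValueError(f"fit subset {fit_domains} has < 3 atoms on the common index")
    ref = ensemble.coords[reference][idx]
    out = np.empty_like(ensemble.coords)
    for k in range(ensemble.n_frames):
        rot, trans = kabsch(ensemble.coords[k][idx], ref)
        out[k] = ensemble.coords[k] @ rot.T + trans
    return StructureEnsemble(
        res_ids=list(ensemble.res_ids),
        coords=out,
        labels=list(ensemble.labels),
        domains=dict(ensemble.domains),
    )


# ---------------------------------------------------------------------------
# structural metrics
# ---------------------------------------------------------------------------

def gap_size(
    chain: CalphaChain,
    domain_a: Iterable[str | int],
    domain_b: Iterable[str | int],
) -> float:
    """Minimal C-alpha/C-alpha distance (Angstrom) between two residue sets."""
    a = chain.select(domain_a)
    b = chain.select(domain_b)
    return float(cdist(a, b).min())


def contact_coordinate(
    probe_xyz: np.ndarray,
    dna_atoms: Sequence[tuple],
    pairing: Mapping | None = None,
) -> tuple[object, str, float]:
    """Nearest DNA backbone contact of a probe atom.

    ``dna_atoms`` is a sequence of ``(strand, base_id, xyz)``.  Returns
    ``(shared_base_id, strand, distance)`` for the closest atom; ``pairing``
    optionally maps one strand's ids onto the shared numbering (the two duplex
    strands share a base id by construction when ``pairing`` is None).
    """
    if len(dna_atoms) == 0:
        raise ValueError("no DNA atoms supplied")
    probe = np.asarray(probe_xyz, dtype=float)
    best = None
    for strand, base_id, xyz in dna_atoms:
        d = float(np.linalg.norm(np.asarray(xyz, dtype=float) - probe))
        if best is None or d < best[2]:
            best = (base_id, strand, d)
    base_id, strand, d = best
    if pairing is not None and (strand, base_id) in pairing:
        base_id = pairing[(strand, base_id)]
    return base_id, strand, d


# ---------------------------------------------------------------------------
# alignments and domain configuration
# ---------------------------------------------------------------------------

def alignment_from_fasta(path: str | Path, query: CalphaChain, homolog: CalphaChain):
    """Read a 2-record gapped FASTA pairwise alignment and return residue pairs.

    Aligned columns with a residue in both records are paired positionally
    against the chains' C-alpha records (record 1 = query, record 2 = subject).
    """
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"expected a pairwise alignment, got {len(records)} records")
    return _pairs_from_gapped(str(records[0].seq), str(records[1].seq), query, homolog)


def _pairs_from_gapped(q_gapped, s_gapped, query, homolog):
    if len(q_gapped) != len(s_gapped):
        raise ValueError("aligned sequences differ in length")
    pairs, qi, si = [], 0, 0
    for qc, sc in zip(q_gapped, s_gapped):
        q_has, s_has = qc not in "-.", sc not in "-."
        if q_has and s_has:
            if qi < len(query.res_ids) and si < len(homolog.res_ids):
                pairs.append((query.res_ids[qi], homolog.res_ids[si]))
        if q_has:
            qi += 1
        if s_has:
            si += 1
    return pairs


def align_sequences(query_seq: str, subject_seq: str):
    """Global Needleman-Wunsch fallback (BLOSUM62, gap open 11 / extend 1).

    Returns the two gapped strings of the best alignment.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    aln = aligner.align(query_seq, subject_seq)[0]
    lines = str(aln).splitlines()
    # biopython "pretty" format: target / match / query rows; rebuild from indices
    q, s = aln[0], aln[1]
    return str(q), str(s)


def load_domain_ranges(path: str | Path | None = None) -> dict:
    """Load domain residue ranges as ``{label: [[start, stop], ...]}``.

    Without a path the packaged UvrD defaults (derived from the closed-state
    crystal structure annotation) are returned.
    """
    if path is None:
        ref = resources.files("forkswitch").joinpath("data/uvrd_domains.json")
        return json.loads(ref.read_text())
    return json.loads(Path(path).read_text())


def domains_from_ranges(ranges: Mapping[str, Sequence[Sequence[int]]]) -> dict:
    """Expand ``{label: [[start, stop], ...]}`` into a residue-id -> label map."""
    out: dict[str, str] = {}
    for label, spans in ranges.items():
        for start, stop in spans:
            for r in range(int(start), int(stop) + 1):
                out[str(r)] = label
    return out
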