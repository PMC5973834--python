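import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from forkswitch import structures as st

from conftest import format_pdb_atom, write_pdb


# ---------------------------------------------------------------------------
# read_calpha
# ---------------------------------------------------------------------------

class TestReadCalpha:
    def test_three_residue_roundtrip(self, three_residue_pdb):
        chain = st.read_calpha(three_residue_pdb, "A")
        assert chain.res_ids == ["1", "2", "3"]
        np.testing.assert_allclose(
            chain.coords, [[1, 0, 0], [2, 0, 0], [3, 0, 0]])

    def test_altloc_highest_occupancy_kept(self, tmp_path):
        lines = [
            format_pdb_atom(1, "CA", "ALA", "A", 1, (9.0, 0.0, 0.0),
                            altloc="A", occupancy=0.3),
            format_pdb_atom(2, "CA", "ALA", "A", 1, (5.0, 0.0, 0.0),
                            altloc="B", occupancy=0.7),
            format_pdb_atom(3, "CA", "GLY", "A", 2, (2.0, 0.0, 0.0)),
            format_pdb_atom(4, "CA", "GLY", "A", 3, (3.0, 0.0, 0.0)),
        ]
        p = tmp_path / "altloc.pdb"
        write_pdb(p, lines)
        chain = st.read_calpha(p, "A")
        assert chain.coords[0][0] == pytest.approx(5.0)

    def test_altloc_tie_keeps_a(self, tmp_path):
        lines = [
            format_pdb_atom(1, "CA", "ALA", "A", 1, (9.0, 0.0, 0.0),
                            altloc="A", occupancy=0.5),
            format_pdb_atom(2, "CA", "ALA", "A", 1, (5.0, 0.0, 0.0),
                            altloc="B", occupancy=0.5),
            format_pdb_atom(3, "CA", "GLY", "A", 2, (2.0, 0.0, 0.0)),
            format_pdb_atom(4, "CA", "GLY", "A", 3, (3.0, 0.0, 0.0)),
        ]
        p = tmp_path / "tie.pdb"
        write_pdb(p, lines)
        chain = st.read_calpha(p, "A")
        assert chain.coords[0][0] == pytest.approx(9.0)

    def test_calpha_less_residue_dropped(self, tmp_path):
        lines = [
            format_pdb_atom(1, "CA", "ALA", "A", 1, (1.0, 0.0, 0.0)),
            format_pdb_atom(2, "N", "GLY", "A", 2, (2.0, 0.0, 0.0)),
            format_pdb_atom(3, "CA", "SER", "A", 3, (3.0, 0.0, 0.0)),
        ]
        p = tmp_path / "gap.pdb"
        write_pdb(p, lines)
        chain = st.read_calpha(p, "A")
        assert len(chain) == 2
        assert chain.res_ids == ["1", "3"]

    def test_missing_chain_raises(self, three_residue_pdb):
        with pytest.raises(ValueError, match="chain"):
            st.read_calpha(three_residue_pdb, "Z")

    def test_extra_atoms_attached(self, tmp_path):
        lines = [
            format_pdb_atom(1, "CA", "THR", "A", 1, (0.0, 0.0, 0.0)),
            format_pdb_atom(2, "OG1", "THR", "A", 1, (0.5, 0.5, 0.5),
                            element="O"),
            format_pdb_atom(3, "CA", "GLY", "A", 2, (1.0, 0.0, 0.0)),
            format_pdb_atom(4, "CA", "GLY", "A", 3, (2.0, 0.0, 0.0)),
        ]
        p = tmp_path / "extra.pdb"
        write_pdb(p, lines)
        chain = st.read_calpha(p, "A", extra_atom_names=("OG1",))
        np.testing.assert_allclose(chain.extra_atoms[("1", "OG1")],
                                   [0.5, 0.5, 0.5])


# ---------------------------------------------------------------------------
# filter_homologs
# ---------------------------------------------------------------------------

class TestFilterHomologs:
    def test_identity_boundary_strict(self):
        hit = st.HomologHit("h", 39.9, 0.9)
        assert st.filter_homologs([hit], 40, 0.6) == []

    def test_coverage_boundary_strict(self):
        hit = st.HomologHit("h", 45.0, 0.59)
        assert st.filter_homologs([hit], 40, 0.6) == []

    def test_mixed_list_hand_enumerated(self):
        hits = [
            st.HomologHit("a", 45.0, 0.7),   # pass
            st.HomologHit("b", 40.0, 0.9),   # identity not strictly above
            st.HomologHit("c", 80.0, 0.6),   # coverage not strictly above
            st.HomologHit("d", 41.0, 0.61),  # pass
            st.HomologHit("e", 10.0, 0.1),   # fail both
        ]
        kept = st.filter_homologs(hits, 40, 0.6)
        assert [h.subject_id for h in kept] == ["a", "d"]

    def test_invalid_hit_rejected(self):
        with pytest.raises(ValueError):
            st.HomologHit("h", 101.0, 0.5)
        with pytest.raises(ValueError):
            st.HomologHit("h", 50.0, 1.5)


# ---------------------------------------------------------------------------
# map_to_query / build_ensemble
# ---------------------------------------------------------------------------

def _chain(coords, start=1):
    coords = np.asarray(coords, dtype=float)
    return st.CalphaChain(
        res_ids=[str(start + i) for i in range(len(coords))],
        res_names=["ALA"] * len(coords),
        coords=coords,
    )


class TestMapping:
    def test_identity_alignment_full_mask(self):
        q = _chain(np.random.default_rng(0).normal(size=(10, 3)))
        frame = st.map_to_query(q, q, [(r, r) for r in q.res_ids])
        assert frame.mask.all()
        np.testing.assert_array_equal(frame.coords, q.coords)

    def test_missing_residues_masked(self):
        rng = np.random.default_rng(1)
        q = _chain(rng.normal(size=(12, 3)))
        # homolog lacks query residues 3..7 (5 residues)
        kept = [r for r in q.res_ids if r not in {"3", "4", "5", "6", "7"}]
        h = st.CalphaChain(res_ids=kept, res_names=["ALA"] * len(kept),
                           coords=q.select(kept))
        frame = st.map_to_query(q, h, [(r, r) for r in kept])
        assert (~frame.mask).sum() == 5
        masked = {q.res_ids[i] for i in np.flatnonzero(~frame.mask)}
        assert masked == {"3", "4", "5", "6", "7"}

    def test_query_insertion_masked_no_shift(self):
        rng = np.random.default_rng(2)
        q = _chain(rng.normal(size=(8, 3)))
        h = _chain(rng.normal(size=(6, 3)), start=101)
        # query residues 4 and 5 are an insertion (unaligned)
        pairs = [("1", "101"), ("2", "102"), ("3", "103"),
                 ("6", "104"), ("7", "105"), ("8", "106")]
        frame = st.map_to_query(q, h, pairs)
        assert not frame.mask[3] and not frame.mask[4]
        np.testing.assert_array_equal(frame.coords[5], h.coords[3])

    def test_absent_residue_raises(self):
        q = _chain(np.zeros((3, 3)) + np.arange(3)[:, None])
        with pytest.raises(KeyError):
            st.map_to_query(q, q, [("1", "99")])

    def test_build_ensemble_intersection(self):
        rng = np.random.default_rng(3)
        q = _chain(rng.normal(size=(10, 3)))
        full = st.map_to_query(q, q, [(r, r) for r in q.res_ids])
        partial = st.map_to_query(
            q, q, [(r, r) for r in q.res_ids if r not in {"2", "9"}])
        ens = st.build_ensemble([full, partial])
        assert len(ens.res_ids) == 8
        assert "2" not in ens.res_ids and "9" not in ens.res_ids

    def test_build_ensemble_identity_keeps_n(self):
        q = _chain(np.random.default_rng(4).normal(size=(7, 3)))
        frames = [st.map_to_query(q, q, [(r, r) for r in q.res_ids])
                  for _ in range(3)]
        ens = st.build_ensemble(frames)
        assert ens.n_atoms == 7 and ens.n_frames == 3

    def test_disjoint_masks_error(self):
        q = _chain(np.random.default_rng(5).normal(size=(6, 3)))
        a = st.map_to_query(q, q, [(r, r) for r in q.res_ids[:3]])
        b = st.map_to_query(q, q, [(r, r) for r in q.res_ids[3:]])
        with pytest.raises(ValueError):
            st.build_ensemble([a, b])


# ---------------------------------------------------------------------------
# superpose
# ---------------------------------------------------------------------------

def _two_domain_ensemble(rng, transform_second=None, rotate_mobile_deg=None):
    static = rng.normal(size=(12, 3))
    mobile = rng.normal(size=(8, 3)) + [12.0, 0, 0]
    ref = np.vstack([static, mobile])
    other = ref.copy()
    if rotate_mobile_deg is not None:
        rot = Rotation.from_euler("z", rotate_mobile_deg, degrees=True)
        center = mobile.mean(axis=0)
        other[12:] = rot.apply(other[12:] - center) + center
    if transform_second is not None:
        rot, trans = transform_second
        other = rot.apply(other) + trans
    res_ids = [str(i + 1) for i in range(20)]
    domains = {r: ("static" if i < 12 else "mobile")
               for i, r in enumerate(res_ids)}
    return st.StructureEnsemble(
        res_ids=res_ids, coords=np.stack([ref, other]),
        labels=["ref", "other"], domains=domains,
    )


class TestSuperpose:
    def test_exact_recovery_of_rigid_copy(self):
        rng = np.random.default_rng(0)
        rot = Rotation.from_euler("xyz", [30, -40, 75], degrees=True)
        ens = _two_domain_ensemble(rng, transform_second=(rot, [5.0, -3.0, 2.0]))
        fitted = st.superpose(ens, fit_domains=["static", "mobile"])
        rmsd = np.sqrt(np.mean(np.sum(
            (fitted.coords[1] - fitted.coords[0]) ** 2, axis=1)))
        assert rmsd < 1e-8

    def test_planted_mobile_rotation_preserved(self):
        rng = np.random.default_rng(1)
        rot = Rotation.from_euler("xyz", [10, 20, 30], degrees=True)
        ens = _two_domain_ensemble(rng, transform_second=(rot, [1.0, 2.0, 3.0]),
                                   rotate_mobile_deg=15.0)
        fitted = st.superpose(ens, fit_domains=["static"])
        static_idx = fitted.atom_indices(["static"])
        mobile_idx = fitted.atom_indices(["mobile"])
        static_rmsd = np.sqrt(np.mean(np.sum(
            (fitted.coords[1][static_idx] - fitted.coords[0][static_idx]) ** 2,
            axis=1)))
        assert static_rmsd < 1e-8
        # mobile displacement equals the planted 15-degree rotation
        mob_ref = ens.coords[0][mobile_idx]
        center = mob_ref.mean(axis=0)
        expected = (Rotation.from_euler("z", 15.0, degrees=True)
                    .apply(mob_ref - center) + center)
        np.testing.assert_allclose(fitted.coords[1][mobile_idx], expected,
                                   atol=1e-8)

    def test_reflection_not_used(self):
        rng = np.random.default_rng(2)
        ens = _two_domain_ensemble(rng)
        coords = ens.coords.copy()
        coords[1] = coords[0] * np.array([1.0, 1.0, -1.0])   # mirror image
        mirrored = st.StructureEnsemble(res_ids=ens.res_ids, coords=coords,
                                        labels=ens.labels, domains=ens.domains)
        fitted = st.superpose(mirrored, fit_domains=["static", "mobile"])
        diff = fitted.coords[1] - fitted.coords[0]
        rmsd = np.sqrt(np.mean(np.sum(diff**2, axis=1)))
        assert rmsd > 0.1
        # oracle: the optimal *proper* rotation found independently agrees
        rot_oracle, _ = Rotation.align_vectors(
            fitted.coords[0] - fitted.coords[0].mean(axis=0),
            mirrored.coords[1] - mirrored.coords[1].mean(axis=0))
        oracle = rot_oracle.apply(
            mirrored.coords[1] - mirrored.coords[1].mean(axis=0)
        ) + fitted.coords[0].mean(axis=0)
        oracle_rmsd = np.sqrt(np.mean(np.sum(
            (oracle - fitted.coords[0]) ** 2, axis=1)))
        assert rmsd == pytest.approx(oracle_rmsd, rel=1e-6)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        rot = Rotation.from_euler("xyz", [5, 15, -25], degrees=True)
        ens = _two_domain_ensemble(rng, transform_second=(rot, [1, 1, 1]),
                                   rotate_mobile_deg=10.0)
        once = st.superpose(ens, fit_domains=["static"])
        twice = st.superpose(once, fit_domains=["static"])
        assert np.max(np.abs(twice.coords - once.coords)) < 1e-9

    def test_kabsch_proper_rotation(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(6, 3))
        rot, trans = st.kabsch(a, a * np.array([1, 1, -1.0]))
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_too_few_fit_atoms(self):
        rng = np.random.default_rng(5)
        ens = _two_domain_ensemble(rng)
        with pytest.raises(ValueError):
            st.superpose(ens, fit_domains=["absent"])


# ---------------------------------------------------------------------------
# gap_size / contact_coordinate
# ---------------------------------------------------------------------------

class TestMetrics:
    def test_shared_point_zero_gap(self):
        chain = _chain([[0, 0, 0], [5, 0, 0], [0, 0, 0]])
        assert st.gap_size(chain, ["1"], ["3"]) == 0.0

    def test_hand_distance(self):
        chain = _chain([[0, 0, 0], [1, 0, 0], [2, 0, 0], [7, 0, 0], [8, 0, 0]])
        assert st.gap_size(chain, ["1", "2", "3"], ["4", "5"]) == pytest.approx(5.0)

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        chain = _chain(rng.normal(size=(10, 3)) * 10)
        a = [str(i) for i in range(1, 6)]
        b = [str(i) for i in range(6, 11)]
        assert st.gap_size(chain, a, b) == st.gap_size(chain, b, a)

    def test_empty_set_raises(self):
        chain = _chain([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(ValueError):
            st.gap_size(chain, ["99"], ["1"])

    def test_contact_single_atom(self):
        base, strand, d = st.contact_coordinate(
            [0, 0, 0], [("A", 7, [3.0, 0.0, 0.0])])
        assert (base, strand, d) == (7, "A", pytest.approx(3.0))

    def test_contact_nearest_wins_with_strand(self):
        base, strand, d = st.contact_coordinate(
            [0, 0, 0],
            [("A", 18, [3.0, 0.0, 0.0]), ("B", 14, [0.0, 2.5, 0.0])])
        assert (base, strand) == (14, "B")
        assert d == pytest.approx(2.5)

    def test_contact_fork_fixture_planted(self):
        # synthetic fork: strand A bases 10..20 along +x at y=+8, strand B
        # (same shared ids) at y=-3; probe sits nearest strand B id 14
        dna = []
        for i in range(10, 21):
            dna.append(("A", i, [float(i), 8.0, 0.0]))
            dna.append(("B", i, [float(i), -3.0, 0.0]))
        base, strand, d = st.contact_coordinate([14.0, 0.0, 0.0], dna)
        assert (base, strand) == (14, "B")
        assert d == pytest.approx(3.0)

    def test_contact_requires_atoms(self):
        with pytest.raises(ValueError):
            st.contact_coordinate([0, 0, 0], [])


# ---------------------------------------------------------------------------
# alignments + domain config
# ---------------------------------------------------------------------------

class TestAlignmentConfig:
    def test_alignment_from_fasta(self, tmp_path):
        rng = np.random.default_rng(0)
        q = _chain(rng.normal(size=(5, 3)))
        h = _chain(rng.normal(size=(4, 3)), start=11)
        fasta = tmp_path / "aln.fasta"
        fasta.write_text(">query\nMKL-V\n>subject\nMK-AV\n")
        pairs = st.alignment_from_fasta(fasta, q, h)
        # columns 1, 2 and 5 are aligned in both sequences; column 5 holds
        # the query's 4th residue (column 4 is a query gap)
        assert pairs == [("1", "11"), ("2", "12"), ("4", "14")]

    def test_needleman_wunsch_fallback_identity(self):
        qg, sg = st.align_sequences("MKLVW", "MKLVW")
        assert qg == sg == "MKLVW"

    def test_default_domain_ranges_load(self):
        ranges = st.load_domain_ranges()
        assert {"1A", "1B", "2A", "2B"} <= set(
            k for k in ranges if not k.startswith("_"))
        domains = st.domains_from_ranges(
            {k: v for k, v in ranges.items() if not k.startswith("_")})
        assert domains["422"] == "2B"    # GIG-motif residue sits in 2B
        assert domains["100"] == "1B"

    def test_no_fabricated_coordinates(self):
        # every ensemble coordinate equals some input coordinate
        rng = np.random.default_rng(6)
        q = _chain(rng.normal(size=(9, 3)))
        h = _chain(rng.normal(size=(9, 3)), start=21)
        pairs = [(str(i + 1), str(21 + i)) for i in range(9)]
        fq = st.map_to_query(q, q, [(r, r) for r in q.res_ids])
        fh = st.map_to_query(q, h, pairs)
        ens = st.build_ensemble([fq, fh])
        pool = np.vstack([q.coords, h.coords])
        for frame in ens.coords:
            for xyz in frame:
                assert np.any(np.all(np.isclose(pool, xyz), axis=1))
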