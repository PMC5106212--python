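"""Coordinate model: I/O round-trips, alt-loc policy, selection, calcium counts."""

import math

import numpy as np
import pytest

from pcdhkit.errors import AnnotationError, EmptyStructureError, FormatError, SelectionError
from pcdhkit.structure import (
    AtomRecord,
    DomainAnnotation,
    ResidueRecord,
    StructureModel,
    count_linker_calcium,
    load_structure,
    read_domain_config,
    select,
    write_structure,
)

ALTLOC_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA AALA A   1      11.639   6.071  -5.147  0.60 10.00           C
ATOM      3  CA BALA A   1      11.700   6.100  -5.200  0.40 10.00           C
ATOM      4  C   ALA A   1      10.674   6.661  -4.127  1.00 10.00           C
ATOM      5  N   GLY A   2       9.902   7.682  -4.480  1.00 10.00           N
ATOM      6  CA  GLY A   2       8.930   8.319  -3.610  1.00 10.00           C
HETATM    7  O   HOH A 101       5.000   5.000   5.000  1.00 20.00           O
END
"""


@pytest.fixture()
def altloc_file(tmp_path):
    path = tmp_path / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    return path


class TestLoadStructure:
    def test_two_residue_fixture_parses_with_correct_ca(self, altloc_file):
        st = load_structure(altloc_file)
        poly = st.polymer_residues()
        assert len(poly) == 2
        np.testing.assert_allclose(poly[1].ca.coords, (8.930, 8.319, -3.610))

    def test_highest_occupancy_altloc_retained(self, altloc_file):
        st = load_structure(altloc_file)
        ca = st.polymer_residues()[0].ca
        assert ca.occupancy == pytest.approx(0.6)
        np.testing.assert_allclose(ca.coords, (11.639, 6.071, -5.147))

    def test_water_flagged_hetero(self, altloc_file):
        st = load_structure(altloc_file)
        waters = [r for r in st.residues() if r.is_water]
        assert len(waters) == 1 and waters[0].is_hetero

    def test_unreadable_file_raises_format_error(self, tmp_path):
        bad = tmp_path / "bad.cif"
        bad.write_text("not a structure at all {{{")
        with pytest.raises((FormatError, EmptyStructureError)):
            load_structure(bad)

    def test_zero_polymer_atoms_raises(self, tmp_path):
        path = tmp_path / "only_water.pdb"
        path.write_text(
            "HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O\nEND\n"
        )
        with pytest.raises(EmptyStructureError):
            load_structure(path)


class TestRoundTrip:
    def test_pdb_round_trip_preserves_counts_and_coords(self, bent_chain, tmp_path):
        structure, _ = bent_chain
        path = tmp_path / "chain.pdb"
        write_structure(structure, path)
        back = load_structure(path)
        assert len(back.atoms()) == len(structure.atoms())
        np.testing.assert_allclose(back.coords(), structure.coords(), atol=1.5e-3)

    def test_pdb_and_mmcif_renderings_agree(self, bent_chain, tmp_path):
        # both dialects written from the one in-memory model must agree to 3 decimals
        structure, _ = bent_chain
        p_pdb, p_cif = tmp_path / "x.pdb", tmp_path / "x.cif"
        write_structure(structure, p_pdb)
        write_structure(structure, p_cif)
        a = load_structure(p_pdb).coords()
        b = load_structure(p_cif).coords()
        np.testing.assert_allclose(a, b, atol=1.5e-3)


class TestSelect:
    def test_domain_selection_matches_annotated_range(self, bent_chain):
        structure, truth = bent_chain
        ann = truth.annotation
        sub = select(structure, "A", domain_labels=["EC4"], annotation=ann)
        label, start, end = truth.planted["domain_ranges"][3]
        assert label == "EC4"
        assert len(sub.polymer_residues()) == end - start + 1
        assert all(start <= r.author_seq_number <= end for r in sub.polymer_residues())

    def test_nested_selection_idempotent(self, bent_chain):
        structure, truth = bent_chain
        ann = truth.annotation
        outer = select(structure, "A", domain_labels=["EC1", "EC2", "EC3"], annotation=ann)
        inner = select(outer, "A", domain_labels=["EC2", "EC3"], annotation=ann)
        direct = select(structure, "A", domain_labels=["EC2", "EC3"], annotation=ann)
        assert [r.author_seq_number for r in inner.polymer_residues()] == [
            r.author_seq_number for r in direct.polymer_residues()
        ]

    def test_range_spanning_two_domains(self, bent_chain):
        # brute-force residue filter as the oracle
        structure, truth = bent_chain
        (_, s1, e1), (_, s2, e2) = truth.planted["domain_ranges"][:2]
        sub = select(structure, "A", seq_range=(s1 + 5, s2 + 5))
        expected = [
            r.author_seq_number
            for r in structure.polymer_residues("A")
            if s1 + 5 <= r.author_seq_number <= s2 + 5
        ]
        assert [r.author_seq_number for r in sub.polymer_residues()] == expected

    def test_disjoint_union_homomorphism(self, bent_chain):
        structure, truth = bent_chain
        ann = truth.annotation
        a = select(structure, "A", domain_labels=["EC1"], annotation=ann)
        b = select(structure, "A", domain_labels=["EC3"], annotation=ann)
        union = select(structure, "A", domain_labels=["EC1", "EC3"], annotation=ann)
        nums = sorted(
            [r.author_seq_number for r in a.polymer_residues()]
            + [r.author_seq_number for r in b.polymer_residues()]
        )
        assert sorted(r.author_seq_number for r in union.polymer_residues()) == nums

    def test_unknown_label_raises(self, bent_chain):
        structure, truth = bent_chain
        with pytest.raises(AnnotationError):
            select(structure, "A", domain_labels=["EC9"], annotation=truth.annotation)

    def test_unknown_chain_raises(self, bent_chain):
        structure, _ = bent_chain
        with pytest.raises(SelectionError):
            select(structure, "Z")


class TestCalciumCounting:
    def test_three_planted_calcium_per_junction(self, bent_chain):
        structure, truth = bent_chain
        table = count_linker_calcium(structure, truth.annotation)
        assert len(table) == 3
        assert (table.n_ca == 3).all()

    def test_no_hetero_atoms_gives_zero(self, straight_chain):
        structure, truth = straight_chain
        table = count_linker_calcium(structure, truth.annotation)
        assert (table.n_ca == 0).all()

    def test_counting_invariant_under_rigid_motion(self, bent_chain, rng):
        structure, truth = bent_chain
        # random proper rotation via QR
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        moved = structure.transformed(q, np.array([12.0, -7.0, 3.0]))
        a = count_linker_calcium(structure, truth.annotation)
        b = count_linker_calcium(moved, truth.annotation)
        assert (a.n_ca == b.n_ca).all()

    def test_missing_annotation_raises(self, bent_chain):
        structure, _ = bent_chain
        with pytest.raises(AnnotationError):
            count_linker_calcium(structure, {})


class TestDomainAnnotation:
    def test_overlapping_ranges_rejected(self):
        with pytest.raises(AnnotationError):
            DomainAnnotation("A", (("EC1", 1, 50), ("EC2", 40, 90)))

    def test_out_of_order_labels_rejected(self):
        with pytest.raises(AnnotationError):
            DomainAnnotation("A", (("EC2", 1, 50), ("EC1", 51, 90)))

    def test_shipped_config_parses_and_covers_cited_entries(self):
        from importlib import resources

        with resources.as_file(
            resources.files("pcdhkit.data") / "domain_boundaries.csv"
        ) as path:
            config = read_domain_config(path)
        for code in ("5szl", "5szp", "5szq", "5szr", "5t9t", "5k8r"):
            assert code in config
        # the membrane-proximal fragments are annotated EC3..EC6
        assert config["5t9t"]["A"].labels == ["EC3", "EC4", "EC5", "EC6"]


class TestInvariantChecks:
    def test_occupancy_outside_unit_interval_rejected(self):
        with pytest.raises(FormatError):
            AtomRecord(1, "CA", "C", "", (0.0, 0.0, 0.0), occupancy=1.5)

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(FormatError):
            AtomRecord(1, "CA", "C", "", (math.nan, 0.0, 0.0))

    def test_insertion_codes_sort_after_base_number(self):
        plain = ResidueRecord("A", 10, "ALA", [])
        inserted = ResidueRecord("A", 10, "ALA", [], insertion_code="A")
        later = ResidueRecord("A", 11, "ALA", [])
        assert plain.seq_key < inserted.seq_key < later.seq_key
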