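"""Structure parsing and six-way micro-classification."""

import io

import pytest

from aluedit.structure import (
    CTParseError,
    IntegrityError,
    PseudoknotError,
    StructureError,
    PairingTable,
    classify_substructures,
    opposite_nucleotide,
    parse_ct,
    parse_dot_bracket,
    site_context,
    to_dot_bracket,
)
from oracle_utils import enumerate_structures, oracle_kind


def ct_text(seq: str, pairs: dict[int, int], energy: float = -1.0) -> str:
    lines = [f"{len(seq)} dG = {energy} test"]
    for i, b in enumerate(seq, start=1):
        lines.append(f"{i} {b} {i-1} {i+1} {pairs.get(i, 0)} {i}")
    return "\n".join(lines) + "\n"


class TestParseCT:
    def test_fully_unpaired_record(self):
        (pt,) = parse_ct(io.StringIO(ct_text("ACGT", {})))
        assert pt.pairs == {}
        assert pt.free_energy == -1.0
        assert pt.sequence == "ACGT"

    def test_pairs_transcribed_symmetrically(self):
        text = ct_text("GGAAAACC", {1: 8, 8: 1, 2: 7, 7: 2})
        (pt,) = parse_ct(text)
        assert pt.pairs == {1: 8, 2: 7, 7: 2, 8: 1}

    def test_asymmetric_pairing_rejected(self):
        text = ct_text("GGAAAACC", {3: 8})  # 8 claims 0
        with pytest.raises(IntegrityError):
            parse_ct(text)

    def test_malformed_column_count_names_line(self):
        text = "2 dG = -1 x\n1 A 0 2 0\n2 A 1 3 0 2\n"
        with pytest.raises(CTParseError, match="line 2"):
            parse_ct(text)

    def test_crossing_pairs_rejected(self):
        text = ct_text("AAAAAA", {1: 4, 4: 1, 2: 6, 6: 2})
        with pytest.raises(PseudoknotError):
            parse_ct(text)

    def test_multi_record_and_energy_capture(self):
        text = ct_text("ACGT", {}, -3.5) + ct_text("GGAAAACC", {1: 8, 8: 1, 2: 7, 7: 2}, -7.25)
        records = parse_ct(text)
        assert [r.free_energy for r in records] == [-3.5, -7.25]

    def test_u_normalized_to_t(self):
        (pt,) = parse_ct(ct_text("ACGU", {}))
        assert pt.sequence == "ACGT"


class TestParseDotBracket:
    @pytest.mark.parametrize(
        "seq,db,expected",
        [
            ("AAAA", "....", {}),
            ("GGAAACC", "((...))", {1: 7, 2: 6, 6: 2, 7: 1}),
        ],
    )
    def test_matching(self, seq, db, expected):
        assert parse_dot_bracket(seq, db).pairs == expected

    def test_unbalanced_rejected(self):
        with pytest.raises(StructureError):
            parse_dot_bracket("GG", ")(")
        with pytest.raises(StructureError):
            parse_dot_bracket("GGG", "((.")

    def test_length_mismatch_rejected(self):
        with pytest.raises(StructureError):
            parse_dot_bracket("GG", "(((...)))")

    def test_round_trip(self):
        db = "((..((....))..))"
        assert to_dot_bracket(parse_dot_bracket("A" * 16, db)) == db


class TestClassification:
    def test_two_helices_interior_and_hairpin(self, example_structure):
        pt, cs = example_structure
        by_kind = {}
        for e in cs:
            by_kind.setdefault(e.kind, []).append(e)
        assert [e.strands for e in by_kind["helix"]] == [
            ((1, 16), (2, 15)),
            ((5, 12), (6, 11)),
        ]
        (interior,) = by_kind["interior"]
        assert interior.strands == ((3, 4), (13, 14))
        (hairpin,) = by_kind["hairpin"]
        assert hairpin.members == (7, 8, 9, 10)

    def test_single_nucleotide_bulge(self):
        pt = parse_dot_bracket("A" * 13, "((.((....))))")
        cs = classify_substructures(pt)
        bulges = [e for e in cs if e.kind == "bulge"]
        assert len(bulges) == 1
        assert bulges[0].members == (3,)
        assert bulges[0].size == 1

    def test_fully_unpaired_is_one_exterior_strand(self):
        pt = parse_dot_bracket("A" * 16, "." * 16)
        cs = classify_substructures(pt)
        assert len(cs) == 1
        assert cs[0].kind == "strand"
        assert cs[0].size == 16

    def test_junction_detected(self):
        db = "((.((...)).((...)).))"
        cs = classify_substructures(parse_dot_bracket("A" * len(db), db))
        kinds = {e.kind for e in cs}
        assert "junction" in kinds

    def test_partition_property(self, example_structure):
        pt, cs = example_structure
        seen = sorted(p for e in cs for p in e.members)
        assert seen == list(range(1, len(pt) + 1))


class TestOracleAgreement:
    def test_exhaustive_small_structures(self):
        """Classifier agrees with the naive loop-decomposition oracle and
        partitions every position, for all valid structures of length <= 10."""
        for db in enumerate_structures(10):
            pt = parse_dot_bracket("A" * len(db), db)
            cs = classify_substructures(pt)
            seen = sorted(p for e in cs for p in e.members)
            assert seen == list(range(1, len(db) + 1)), db
            kind_of = cs.kind_of
            for pos in range(1, len(db) + 1):
                assert kind_of[pos] == oracle_kind(db, pos), (db, pos)


def mirror(db: str) -> str:
    return db[::-1].translate(str.maketrans("()", ")("))


class TestSiteContext:
    def test_interior_edge_site(self, example_structure):
        pt, cs = example_structure
        c = site_context(pt, cs, 3)
        assert (c.kind, c.strand_len, c.opp_strand_len, c.asymmetry, c.ce_pos) == (
            "interior", 2, 2, 0, 0,
        )
        assert c.helix_flank == "upstream-only"  # position 2 paired, 4 unpaired

    def test_helix_terminus(self, example_structure):
        pt, cs = example_structure
        c = site_context(pt, cs, 5)
        assert (c.kind, c.ce_pos, c.strand_len) == ("helix", 0, 2)

    def test_middle_of_11bp_helix(self):
        db = "(" * 11 + "..." + ")" * 11
        pt = parse_dot_bracket("A" * len(db), db)
        cs = classify_substructures(pt)
        c = site_context(pt, cs, 6)
        assert (c.kind, c.ce_pos) == ("helix", 5)

    def test_neighbors_follow_primary_sequence(self, example_structure):
        pt, cs = example_structure
        c = site_context(pt, cs, 3, k_max=5)
        assert c.up_nbr(1) == pt.sequence[1]
        assert c.dn_nbr(1) == pt.sequence[3]
        assert c.up_nbr(3) is None  # beyond record start
        assert c.dn_nbr(5) == pt.sequence[7]

    def test_out_of_range_position(self, example_structure):
        pt, cs = example_structure
        with pytest.raises(IndexError):
            site_context(pt, cs, 17)

    def test_mirror_symmetry(self):
        """Reversing the sequence and mirroring pairs preserves kind, cePos,
        strand lengths and |asymmetry| of every site."""
        for db in enumerate_structures(10):
            pt = parse_dot_bracket("A" * len(db), db)
            cs = classify_substructures(pt)
            mdb = mirror(db)
            mpt = parse_dot_bracket("A" * len(mdb), mdb)
            mcs = classify_substructures(mpt)
            n = len(db)
            for pos in range(1, n + 1):
                c = site_context(pt, cs, pos)
                m = site_context(mpt, mcs, n + 1 - pos)
                assert (c.kind, c.ce_pos, c.strand_len, c.opp_strand_len) == (
                    m.kind, m.ce_pos, m.strand_len, m.opp_strand_len,
                ), (db, pos)
                if c.asymmetry is not None:
                    assert abs(c.asymmetry) == abs(m.asymmetry)


class TestOppositeNucleotide:
    def test_loop_edge_maps_5prime_to_3prime(self, example_structure):
        pt, cs = example_structure
        assert opposite_nucleotide(pt, cs, 3) == pt.sequence[13]
        assert opposite_nucleotide(pt, cs, 4) == pt.sequence[12]

    def test_helix_partner_base(self, example_structure):
        pt, cs = example_structure
        assert opposite_nucleotide(pt, cs, 5) == pt.sequence[11]

    def test_single_ac_mismatch(self):
        # A.C mismatch: 1x1 interior loop inside a helix -> opposite is the C
        seq = "GGACCGAAACGGCCC"
        db = "((.(((...))).))"
        pt = parse_dot_bracket(seq, db)
        cs = classify_substructures(pt)
        c = site_context(pt, cs, 3)
        assert c.base == "A"
        assert c.kind == "interior" and c.strand_len == 1 and c.opp_strand_len == 1
        assert c.helix_flank == "both"
        assert opposite_nucleotide(pt, cs, 3) == "C"

    def test_undefined_when_own_strand_1_opposite_longer(self):
        db = "((.((...))...))"
        pt = parse_dot_bracket("A" * len(db), db)
        cs = classify_substructures(pt)
        c = site_context(pt, cs, 3)
        assert c.kind == "interior" and c.strand_len == 1 and c.opp_strand_len == 3
        assert opposite_nucleotide(pt, cs, 3) == "undefined"

    def test_non_edge_and_other_kinds_not_applicable(self):
        db = "((..((...))...))"  # 2x3 interior loop
        pt = parse_dot_bracket("A" * len(db), db)
        cs = classify_substructures(pt)
        assert opposite_nucleotide(pt, cs, 12) == "A"  # 5'-most -> 3'-most of 2-strand
        assert opposite_nucleotide(pt, cs, 13) == "n/a"  # cePos > 0
        assert opposite_nucleotide(pt, cs, 8) == "n/a"  # hairpin

    def test_reciprocity_on_enumerated_loops(self):
        """If opNuc of i is the base at j via the loop-edge rule and opNuc of
        j is defined, it must point back at i (checked via distinct bases)."""
        for db in enumerate_structures(10):
            seq = "ACGTACGTACGT"[: len(db)]
            pt = parse_dot_bracket(seq, db)
            cs = classify_substructures(pt)
            for e in cs:
                if e.kind != "interior":
                    continue
                (s1, e1), (s2, e2) = e.strands
                if e1 - s1 == e2 - s2:  # symmetric loop: rule is reciprocal
                    assert opposite_nucleotide(pt, cs, s1) == seq[e2 - 1]
                    assert opposite_nucleotide(pt, cs, e2) == seq[s1 - 1]


class TestPairingTableValidation:
    def test_self_pair_rejected(self):
        with pytest.raises(IntegrityError):
            PairingTable("ACGT", {2: 2})

    def test_asymmetric_rejected(self):
        with pytest.raises(IntegrityError):
            PairingTable("ACGTA", {1: 5, 5: 2, 2: 5})

    def test_crossing_rejected(self):
        with pytest.raises(PseudoknotError):
            PairingTable("ACGTAC", {1: 4, 4: 1, 2: 6, 6: 2})
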