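"""Read classification, junction counting and intron evidence."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deltasi.junctions import (
    AlignedRead,
    ReadGroup,
    classify_read,
    collect_intron_evidence,
    extract_junction_counts,
    read_sj_tab,
)


def mk_read(pos, cigar, chrom="chr1", sample="s1", rid="r"):
    return AlignedRead(read_id=rid, chrom=chrom, pos=pos, cigar=cigar,
                       sample_id=sample)


class TestClassifyRead:
    def test_gap_read_over_intron_is_exon_exon(self, tiny_index):
        read = mk_read(180, [("M", 20), ("N", 100), ("M", 20)])
        assert classify_read(read, tiny_index) is ReadGroup.EXON_EXON

    def test_border_bridging_read_is_exon_intron(self, tiny_index):
        # [190, 230) crosses the border at 200 with 10 exon-side / 30 intron-side
        read = mk_read(190, [("M", 40)])
        assert classify_read(read, tiny_index, min_overhang=6) is ReadGroup.EXON_INTRON

    def test_fully_intronic_read(self, tiny_index):
        read = mk_read(220, [("M", 40)])
        assert classify_read(read, tiny_index) is ReadGroup.INTRONIC

    def test_short_gap_anchor_demotes_to_other(self, tiny_index):
        read = mk_read(196, [("M", 4), ("N", 100), ("M", 40)])
        assert classify_read(read, tiny_index, min_overhang=6) is ReadGroup.OTHER

    def test_exonic_read_is_other(self, tiny_index):
        read = mk_read(110, [("M", 40)])
        assert classify_read(read, tiny_index) is ReadGroup.OTHER

    def test_border_needs_overhang_on_both_sides(self, tiny_index):
        # [197, 237): 3 nt on the exon side of border 200 — neither a border
        # read (overhang short) nor intronic (not fully contained)
        read = mk_read(197, [("M", 40)])
        assert classify_read(read, tiny_index, min_overhang=6) is ReadGroup.OTHER

    def test_gap_takes_precedence_over_border(self, tiny_index):
        # anchored gap plus a block over a border: still Group 1
        read = mk_read(190, [("M", 20), ("N", 90), ("M", 20)])
        assert classify_read(read, tiny_index) is ReadGroup.EXON_EXON


class TestJunctionCounts:
    def test_no_reads_empty_counts(self):
        jc = extract_junction_counts([])
        assert jc.keys() == []

    def test_identical_reads_are_additive(self):
        reads = [mk_read(180, [("M", 20), ("N", 100), ("M", 20)], rid=f"r{i}")
                 for i in range(3)]
        jc = extract_junction_counts(reads)
        assert jc.get(("chr1", 200, 300), "s1") == 3

    def test_multi_gap_read_increments_each_junction(self):
        read = mk_read(100, [("M", 10), ("N", 50), ("M", 10), ("N", 30), ("M", 10)])
        jc = extract_junction_counts(read for read in [read])
        assert jc.get(("chr1", 110, 160), "s1") == 1
        assert jc.get(("chr1", 170, 200), "s1") == 1

    def test_order_invariance(self):
        reads = [
            mk_read(180, [("M", 20), ("N", 100), ("M", 20)], rid="a"),
            mk_read(100, [("M", 10), ("N", 50), ("M", 10)], rid="b"),
            mk_read(180, [("M", 20), ("N", 100), ("M", 20)], rid="c", sample="s2"),
        ]
        jc1 = extract_junction_counts(list(reads))
        rng = random.Random(0)
        shuffled = list(reads)
        rng.shuffle(shuffled)
        jc2 = extract_junction_counts(shuffled)
        assert jc1.to_frame().equals(jc2.to_frame())

    @given(
        anchors=st.lists(
            st.tuples(st.integers(1, 30), st.integers(1, 30)), min_size=1, max_size=20
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_anchor_monotonicity(self, anchors):
        """Raising min_overhang never increases any junction count."""
        reads = [
            mk_read(200 - a, [("M", a), ("N", 100), ("M", b)], rid=f"r{i}")
            for i, (a, b) in enumerate(anchors)
        ]
        lo = extract_junction_counts(reads, min_overhang=4)
        hi = extract_junction_counts(reads, min_overhang=12)
        for coords in set(lo.keys()) | set(hi.keys()):
            assert hi.get(coords, "s1") <= lo.get(coords, "s1")

    def test_cigar_insertion_softclip_consume_no_reference(self):
        read = mk_read(180, [("S", 5), ("M", 10), ("I", 3), ("M", 10),
                             ("N", 100), ("M", 20)])
        jc = extract_junction_counts([read])
        assert jc.get(("chr1", 200, 300), "s1") == 1

    def test_deletion_does_not_create_a_junction(self):
        read = mk_read(180, [("M", 10), ("D", 5), ("M", 10)])
        jc = extract_junction_counts([read])
        assert jc.keys() == []


class TestSJTab:
    def test_star_row_converted_to_half_open(self, tmp_path):
        p = tmp_path / "sj.tab"
        p.write_text("chr1\t201\t300\t1\t1\t1\t7\t0\t20\n")
        jc = read_sj_tab(p, "s1")
        assert jc.get(("chr1", 200, 300), "s1") == 7
        assert jc.strand[("chr1", 200, 300)] == "+"

    def test_empty_file(self, tmp_path):
        p = tmp_path / "sj.tab"
        p.write_text("")
        assert read_sj_tab(p, "s1").keys() == []

    def test_bad_column_count_rejected(self, tmp_path):
        p = tmp_path / "sj.tab"
        p.write_text("chr1\t201\t300\t1\n")
        with pytest.raises(ValueError, match="9 columns"):
            read_sj_tab(p, "s1")

    def test_unknown_strand_resolved_by_unique_gene_overlap(self, tmp_path, tiny_index):
        p = tmp_path / "sj.tab"
        p.write_text("chr2\t1101\t1300\t0\t0\t0\t5\t0\t20\n")
        jc = read_sj_tab(p, "s1")
        assert jc.strand[("chr2", 1100, 1300)] == "."
        jc.resolve_strands(tiny_index)
        assert jc.strand[("chr2", 1100, 1300)] == "-"  # GD is minus-strand


class TestIntronEvidence:
    def test_untouched_intron_yields_zero_record(self, tiny_index):
        ev = collect_intron_evidence([], tiny_index)
        rec = ev.get(("chr1", 200, 300), "s1")
        assert rec.left_boundary_count == rec.intronic_read_count == 0
        assert rec.covered_fraction == 0.0

    def test_single_intronic_read_coverage(self, tiny_index):
        # one 40M read fully inside the 100 nt intron [200, 300)
        ev = collect_intron_evidence([mk_read(220, [("M", 40)])], tiny_index)
        rec = ev.get(("chr1", 200, 300), "s1")
        assert rec.intronic_read_count == 1
        assert rec.covered_fraction == pytest.approx(0.4)
        assert rec.mean_depth == pytest.approx(0.4)

    def test_boundary_reads_assigned_to_matching_border(self, tiny_index):
        reads = [mk_read(190, [("M", 40)], rid=f"l{i}") for i in range(2)]
        reads += [mk_read(280, [("M", 40)], rid=f"r{i}") for i in range(4)]
        ev = collect_intron_evidence(reads, tiny_index)
        rec = ev.get(("chr1", 200, 300), "s1")
        assert rec.left_boundary_count == 2
        assert rec.right_boundary_count == 4
        assert rec.intronic_read_count == 0

    def test_group_conservation(self, tiny_index):
        reads = [
            mk_read(180, [("M", 20), ("N", 100), ("M", 20)]),
            mk_read(190, [("M", 40)]),
            mk_read(220, [("M", 40)]),
            mk_read(110, [("M", 40)]),
            mk_read(196, [("M", 4), ("N", 100), ("M", 40)]),
        ]
        groups = [classify_read(r, tiny_index) for r in reads]
        assert len(groups) == len(reads)
        assert groups.count(ReadGroup.EXON_EXON) == 1
        assert groups.count(ReadGroup.EXON_INTRON) == 1
        assert groups.count(ReadGroup.INTRONIC) == 1
        assert groups.count(ReadGroup.OTHER) == 2

    def test_evidence_tsv_round_trip(self, tiny_index, tmp_path):
        from deltasi.junctions import EvidenceTable

        reads = [mk_read(190, [("M", 40)]), mk_read(220, [("M", 40)])]
        ev = collect_intron_evidence(reads, tiny_index)
        p = tmp_path / "ev.tsv"
        ev.to_tsv(p)
        back = EvidenceTable.from_tsv(p)
        assert back.to_frame().equals(ev.to_frame())
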