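"""Candidate event enumeration and known/novel labelling."""

import pytest

from deltasi.annotation import (
    GeneModel,
    GenomicInterval,
    Transcript,
    build_annotation_index,
)
from deltasi.events import (
    EventType,
    detect_alt_first_exon,
    detect_alt_ss,
    detect_events,
    detect_exon_skipping,
    detect_intron_retention,
    label_novel,
)
from deltasi.junctions import EvidenceTable, JunctionCounts


def jc_with(counts, strand="+"):
    jc = JunctionCounts()
    for coords, n in counts.items():
        jc.add(coords, "s1", n, strand)
    return jc


@pytest.fixture(scope="module")
def skip_free_index():
    """GA-like gene whose annotation has no skip isoform."""
    t1 = Transcript(
        "GX.t1", "GX", "+",
        [GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 300, 400),
         GenomicInterval("chr1", 500, 600)],
    )
    return build_annotation_index([GeneModel("GX", "GX", "+", "chr1", [t1])])


class TestExonSkipping:
    def test_observed_triple_yields_one_event(self, tiny_index):
        jc = jc_with({("chr1", 200, 300): 10, ("chr1", 400, 500): 12,
                      ("chr1", 200, 500): 7})
        events = detect_exon_skipping(jc, tiny_index)
        assert len(events) == 1
        (e,) = events
        assert e.skip == ("chr1", 200, 500)
        assert e.upstream == ("chr1", 200, 300)
        assert e.downstream == ("chr1", 400, 500)
        assert "300-400" in e.event_id  # middle exon from junction geometry
        assert e.novel is False  # skip isoform GA.t2 is annotated

    def test_no_event_without_skip_junction(self, skip_free_index):
        jc = jc_with({("chr1", 200, 300): 10, ("chr1", 400, 500): 12})
        assert detect_exon_skipping(jc, skip_free_index) == []

    def test_unannotated_skip_junction_is_novel(self, skip_free_index):
        jc = jc_with({("chr1", 200, 300): 10, ("chr1", 400, 500): 12,
                      ("chr1", 200, 500): 7})
        (e,) = detect_exon_skipping(jc, skip_free_index)
        assert e.novel is True

    def test_middle_exon_length_guard(self, skip_free_index):
        jc = jc_with({("chr1", 200, 300): 10, ("chr1", 400, 500): 12,
                      ("chr1", 200, 500): 7})
        assert detect_exon_skipping(jc, skip_free_index, max_middle_exon=50) == []


class TestAltSpliceSites:
    def test_shared_acceptor_gives_alt5ss(self, skip_free_index):
        jc = jc_with({("chr1", 200, 400): 30, ("chr1", 250, 400): 10})
        events = [e for e in detect_alt_ss(jc, skip_free_index, "5SS",
                                           control_sample="s1")
                  if e.variant_j == ("chr1", 250, 400)]
        assert len(events) == 1
        (e,) = events
        assert e.etype is EventType.ALT_5SS
        assert e.canonical_j == ("chr1", 200, 400)  # higher control count

    def test_shared_donor_gives_alt3ss(self, skip_free_index):
        jc = jc_with({("chr1", 210, 400): 30, ("chr1", 210, 450): 10})
        events = [e for e in detect_alt_ss(jc, skip_free_index, "3SS",
                                           control_sample="s1")
                  if e.variant_j == ("chr1", 210, 450)]
        assert len(events) == 1
        assert events[0].etype is EventType.ALT_3SS
        assert events[0].canonical_j == ("chr1", 210, 400)

    def test_single_donor_per_acceptor_yields_nothing(self, skip_free_index):
        jc = jc_with({("chr1", 200, 400): 30})
        assert detect_alt_ss(jc, skip_free_index, "5SS") == []

    def test_annotated_junction_is_canonical(self, tiny_index):
        # (200,300) is annotated; the observed competitor is not
        jc = jc_with({("chr1", 200, 300): 5, ("chr1", 240, 300): 50})
        events = [
            e for e in detect_alt_ss(jc, tiny_index, "5SS", control_sample="s1")
            if e.variant_j == ("chr1", 240, 300)
        ]
        assert len(events) == 1
        assert events[0].canonical_j == ("chr1", 200, 300)
        assert events[0].novel is True

    def test_three_competitors_pairwise_against_canonical(self, skip_free_index):
        jc = jc_with({("chr1", 210, 400): 50, ("chr1", 230, 400): 10,
                      ("chr1", 260, 400): 8})
        events = detect_alt_ss(jc, skip_free_index, "5SS", control_sample="s1")
        assert len(events) == 2
        assert all(e.canonical_j == ("chr1", 210, 400) for e in events)

    def test_strandless_groups_skipped(self):
        # no annotation: junction strand cannot be resolved
        index = build_annotation_index([])
        jc = JunctionCounts()
        jc.add(("chr9", 100, 200), "s1", 5)
        jc.add(("chr9", 120, 200), "s1", 5)
        assert detect_alt_ss(jc, index, "5SS") == []


class TestAltFirstExon:
    def test_two_annotated_first_exons_give_two_events(self, tiny_index):
        jc = jc_with({("chr1", 10100, 10300): 20, ("chr1", 10250, 10300): 15})
        events = detect_alt_first_exon(jc, tiny_index)
        gb = [e for e in events if e.gene_id == "GB"]
        assert len(gb) == 2
        assert {e.variant_j for e in gb} == {
            ("chr1", 10100, 10300), ("chr1", 10250, 10300)
        }
        assert all(e.novel is False for e in gb)

    def test_single_first_exon_gene_yields_nothing(self, skip_free_index):
        jc = jc_with({("chr1", 200, 300): 20})
        assert detect_alt_first_exon(jc, skip_free_index) == []

    def test_novel_first_exon_donor_detected(self, tiny_index):
        # observed donor outside annotated exons splicing into the
        # first-exon acceptor at 10300
        jc = jc_with({("chr1", 10100, 10300): 20, ("chr1", 10250, 10300): 15,
                      ("chr1", 10280, 10300): 9})
        events = [e for e in detect_alt_first_exon(jc, tiny_index)
                  if e.gene_id == "GB"]
        assert len(events) == 3
        novel = [e for e in events if e.novel]
        assert len(novel) == 1
        assert novel[0].variant_j == ("chr1", 10280, 10300)

    def test_afe_donors_not_double_counted_as_alt5ss(self, tiny_index):
        jc = jc_with({("chr1", 10100, 10300): 20, ("chr1", 10250, 10300): 15})
        events = detect_events(jc, EvidenceTable(), tiny_index, control_sample="s1")
        a5 = [e for e in events if e.etype is EventType.ALT_5SS
              and e.variant_j in {("chr1", 10100, 10300), ("chr1", 10250, 10300)}]
        assert a5 == []


class TestIntronRetention:
    def test_spliced_only_intron_emits_event(self, tiny_index):
        jc = jc_with({("chr1", 200, 300): 20})
        events = detect_intron_retention(jc, EvidenceTable(), tiny_index)
        ids = {e.intron for e in events}
        assert ("chr1", 200, 300) in ids

    def test_boundary_only_novel_interval_is_novel_event(self, tiny_index):
        jc = jc_with({("chr1", 240, 290): 3})  # novel junction defines interval
        events = detect_intron_retention(jc, EvidenceTable(), tiny_index)
        e = next(ev for ev in events if ev.intron == ("chr1", 240, 290))
        assert e.novel is True

    def test_annotated_intron_without_retention_isoform_is_novel(self, tiny_index):
        jc = jc_with({("chr1", 400, 500): 20})
        e = next(ev for ev in detect_intron_retention(jc, EvidenceTable(), tiny_index)
                 if ev.intron == ("chr1", 400, 500))
        assert e.novel is True  # retention state unannotated

    def test_annotated_retention_isoform_makes_event_known(self):
        t1 = Transcript(
            "GR.t1", "GR", "+",
            [GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 300, 400)],
        )
        tr = Transcript("GR.t2", "GR", "+", [GenomicInterval("chr1", 100, 400)])
        index = build_annotation_index([GeneModel("GR", "GR", "+", "chr1", [t1, tr])])
        jc = jc_with({("chr1", 200, 300): 20})
        (e,) = detect_intron_retention(jc, EvidenceTable(), index)
        assert e.intron == ("chr1", 200, 300)
        assert e.novel is False

    def test_no_evidence_no_event(self, tiny_index):
        events = detect_intron_retention(JunctionCounts(), EvidenceTable(), tiny_index)
        assert events == []


class TestNovelLabel:
    def test_all_annotated_keys_not_novel(self, tiny_index):
        assert label_novel({("chr1", 200, 300)}, {("chr1", 400, 500)}, tiny_index) is False

    def test_any_unannotated_key_is_novel(self, tiny_index):
        assert label_novel({("chr1", 201, 300)}, {("chr1", 400, 500)}, tiny_index) is True


class TestDetectEvents:
    def test_deterministic_and_unique(self, small_sim):
        e1 = detect_events(small_sim.junctions, small_sim.evidence, small_sim.index,
                           control_sample="normoxia")
        e2 = detect_events(small_sim.junctions, small_sim.evidence, small_sim.index,
                           control_sample="normoxia")
        assert [e.event_id for e in e1] == [e.event_id for e in e2]
        sigs = [(e.etype, e.variant_form) for e in e1]
        assert len(sigs) == len(set(sigs))

    def test_every_supported_truth_event_is_a_candidate(self, small_sim):
        events = detect_events(small_sim.junctions, small_sim.evidence,
                               small_sim.index, control_sample="normoxia")
        ids = {e.event_id for e in events}
        for t in small_sim.truth.events:
            assert t.event_id in ids, t.event_id
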