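"""Shared fixtures: hand-built gene models plus a small simulated dataset."""

from dataclasses import dataclass

import pytest

from deltasi.annotation import (
    GeneModel,
    GenomicInterval,
    Transcript,
    build_annotation_index,
)
from deltasi.simulate import SimulationConfig, simulate_dataset


def iv(chrom, start, end, strand="+"):
    return GenomicInterval(chrom, start, end, strand)


@pytest.fixture(scope="session")
def tiny_genes():
    """Three-exon gene with an annotated skip isoform, a two-first-exon gene,
    a single-exon gene, and a minus-strand gene."""
    ga_t1 = Transcript(
        "GA.t1", "GA", "+",
        [iv("chr1", 100, 200), iv("chr1", 300, 400), iv("chr1", 500, 600)],
    )
    ga_t2 = Transcript(
        "GA.t2", "GA", "+", [iv("chr1", 100, 200), iv("chr1", 500, 600)]
    )
    ga = GeneModel("GA", "GA", "+", "chr1", [ga_t1, ga_t2])

    gb_t1 = Transcript(
        "GB.t1", "GB", "+",
        [iv("chr1", 10000, 10100), iv("chr1", 10300, 10400), iv("chr1", 10600, 10700)],
    )
    gb_t2 = Transcript(
        "GB.t2", "GB", "+",
        [iv("chr1", 10150, 10250), iv("chr1", 10300, 10400), iv("chr1", 10600, 10700)],
    )
    gb = GeneModel("GB", "GB", "+", "chr1", [gb_t1, gb_t2])

    gc = GeneModel(
        "GC", "GC", "+", "chr1",
        [Transcript("GC.t1", "GC", "+", [iv("chr1", 20000, 20500)])],
    )

    gd_t1 = Transcript(
        "GD.t1", "GD", "-",
        [iv("chr2", 1000, 1100, "-"), iv("chr2", 1300, 1400, "-"),
         iv("chr2", 1600, 1700, "-")],
    )
    gd = GeneModel("GD", "GD", "-", "chr2", [gd_t1])
    return [ga, gb, gc, gd]


@pytest.fixture(scope="session")
def tiny_index(tiny_genes):
    return build_annotation_index(tiny_genes)


@dataclass
class SimData:
    cfg: SimulationConfig
    genes: list
    truth: object
    junctions: object
    evidence: object
    gene_counts: dict
    index: object


@pytest.fixture(scope="session")
def small_sim():
    """Desk-scale simulated dataset (count level, no alignments)."""
    cfg = SimulationConfig(n_genes=60)
    genes, truth, jc, ev, gcounts, _ = simulate_dataset(cfg, seed=5)
    index = build_annotation_index(genes)
    jc.resolve_strands(index)
    return SimData(cfg, genes, truth, jc, ev, gcounts, index)
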