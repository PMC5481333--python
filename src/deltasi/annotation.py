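"""Gene-model ingestion and splice-junction indexing.

All coordinates are 0-based half-open internally; GTF (1-based inclusive) is
converted exactly once at the I/O boundary.  A splice junction is identified
by its intron interval ``(chrom, intron_start, intron_end, strand)`` — the
same interval a spliced alignment reports as its N gap.

The :class:`AnnotationIndex` built here is the reference set against which
observed splicing is labelled *known* or *novel*: it indexes every junction
derivable from a consecutive exon pair, every first-exon donor junction per
gene (alternative promoter usage), consecutive-junction pairs (cassette-exon
frames), and per-gene exonic unions for expression counting.
"""

from __future__ import annotations

import bisect
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional

from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")


class GTFParseError(ValueError):
    pass


class ValidationError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("empty chrom")
        if not self.start < self.end:
            raise ValidationError(
                f"interval start must precede end: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass(frozen=True, order=True)
class JunctionKey:
    """A splice junction, identified by its intron interval.

    ``intron_start`` is the first intronic base (0-based); ``intron_end`` is
    exclusive.  Strand ``"."`` marks a junction whose strand could not be
    resolved from the alignments.
    """

    chrom: str
    intron_start: int
    intron_end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.intron_start < self.intron_end:
            raise ValidationError(
                f"junction start must precede end: "
                f"{self.chrom}:{self.intron_start}-{self.intron_end}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"bad strand {self.strand!r}")

    @property
    def coords(self) -> tuple:
        return (self.chrom, self.intron_start, self.intron_end)

    @property
    def length(self) -> int:
        return self.intron_end - self.intron_start


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    strand: str
    exons: list  # of GenomicInterval, sorted by start

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id} has no exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        chroms = {e.chrom for e in self.exons}
        if len(chroms) != 1:
            raise ValidationError(
                f"transcript {self.transcript_id} spans multiple chroms {chroms}"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"transcript {self.transcript_id} has overlapping exons "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def introns(self) -> list:
        """Gaps between consecutive exons, as JunctionKeys."""
        return [
            JunctionKey(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
        ]

    @property
    def first_exon(self) -> GenomicInterval:
        """5'-most exon respecting strand (unknown strand treated as +)."""
        return self.exons[-1] if self.strand == "-" else self.exons[0]

    @property
    def first_exon_donor(self) -> Optional[JunctionKey]:
        """The junction leaving the first exon, or None for 1-exon transcripts."""
        if len(self.exons) < 2:
            return None
        if self.strand == "-":
            return JunctionKey(
                self.chrom, self.exons[-2].end, self.exons[-1].start, self.strand
            )
        return JunctionKey(
            self.chrom, self.exons[0].end, self.exons[1].start, self.strand
        )


@dataclass
class GeneModel:
    gene_id: str
    gene_name: str
    strand: str
    chrom: str
    transcripts: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValidationError(f"gene {self.gene_id} has no transcripts")
        for t in self.transcripts:
            if t.gene_id != self.gene_id or t.chrom != self.chrom or t.strand != self.strand:
                raise ValidationError(
                    f"transcript {t.transcript_id} inconsistent with gene {self.gene_id}"
                )
        self.transcripts = sorted(
            self.transcripts, key=lambda t: (t.start, t.transcript_id)
        )

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    @property
    def exonic_union(self) -> list:
        """Merged exon intervals over all transcripts, as (start, end) tuples."""
        ivs = sorted((e.start, e.end) for t in self.transcripts for e in t.exons)
        merged = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return merged


# ---------------------------------------------------------------------------
# GTF I/O


def _parse_attributes(raw: str, lineno: int) -> dict:
    attrs = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            raise GTFParseError(f"line {lineno}: malformed attribute {chunk!r}")
        attrs[parts[0]] = parts[1].strip().strip('"')
    return attrs


def read_gtf(path) -> list:
    """Read Ensembl-style GTF into validated gene models.

    Only ``exon`` features are used.  1-based inclusive coordinates are
    converted to 0-based half-open here and nowhere else.
    """
    tx_exons: dict = {}
    tx_meta: dict = {}
    gene_names: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GTFParseError(
                    f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _source, feature, start, end, _score, strand, _frame, attr = fields
            if feature != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise GTFParseError(f"line {lineno}: non-integer coordinates") from None
            if start_i < 1 or end_i < start_i:
                raise GTFParseError(f"line {lineno}: bad coordinates {start}-{end}")
            attrs = _parse_attributes(attr, lineno)
            if "transcript_id" not in attrs:
                raise GTFParseError(f"line {lineno}: exon lacks transcript_id")
            if "gene_id" not in attrs:
                raise GTFParseError(f"line {lineno}: exon lacks gene_id")
            tid, gid = attrs["transcript_id"], attrs["gene_id"]
            if strand not in ("+", "-"):
                strand = "."
            iv = GenomicInterval(chrom, start_i - 1, end_i, strand)
            tx_exons.setdefault(tid, []).append(iv)
            tx_meta[tid] = (gid, chrom, strand)
            gene_names.setdefault(gid, attrs.get("gene_name", gid))

    by_gene: dict = defaultdict(list)
    for tid in sorted(tx_exons):
        gid, chrom, strand = tx_meta[tid]
        by_gene[gid].append(Transcript(tid, gid, strand, tx_exons[tid]))

    genes = []
    for gid in by_gene:
        txs = by_gene[gid]
        genes.append(
            GeneModel(gid, gene_names[gid], txs[0].strand, txs[0].chrom, txs)
        )
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def write_gtf(genes: Iterable, path) -> None:
    """Write gene models back to Ensembl-style GTF (exon features only)."""
    with open(path, "w") as fh:
        for gene in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            for tx in gene.transcripts:
                for iv in tx.exons:
                    attrs = (
                        f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}"; '
                        f'gene_name "{gene.gene_name}";'
                    )
                    fh.write(
                        "\t".join(
                            [
                                gene.chrom,
                                "deltasi",
                                "exon",
                                str(iv.start + 1),
                                str(iv.end),
                                ".",
                                gene.strand if gene.strand in ("+", "-") else ".",
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )


# ---------------------------------------------------------------------------
# Index


class AnnotationIndex:
    """Derived lookup structures over a set of gene models.

    known_junctions / known_introns
        every distinct consecutive-exon gap over all transcripts.
    first_exon_donors
        per gene: {(first-exon coords, donor JunctionKey)} for each distinct
        first exon with a downstream junction.
    exon_triples
        annotated consecutive junction pairs (u, d) — each frames a cassette
        (middle) exon [u.end, d.start).
    retention_known
        intron coords for which some annotated transcript carries an exon
        spanning the whole intron (annotated intron retention).
    """

    def __init__(self, genes: Iterable):
        self.genes = {g.gene_id: g for g in genes}
        self.known_junctions: set = set()
        self._known_coords: set = set()
        self._strand_by_coords: dict = {}
        self.first_exon_donors: dict = defaultdict(set)
        self.exon_triples: set = set()
        self.retention_known: set = set()
        self.intron_genes: dict = defaultdict(set)  # coords -> gene_ids

        self._gene_tree: dict = defaultdict(IntervalTree)
        self._exon_tree: dict = defaultdict(IntervalTree)
        self._intron_tree: dict = defaultdict(IntervalTree)
        self._borders: dict = defaultdict(list)  # chrom -> sorted positions
        self._border_introns: dict = defaultdict(list)  # (chrom,pos) -> [(key, side)]
        self._acceptors: dict = defaultdict(set)  # gene_id -> acceptor positions
        self._exon_spans: dict = {}  # chrom -> sorted exon intervals (merged)

        for g in self.genes.values():
            self._gene_tree[g.chrom].addi(g.start, g.end, g.gene_id)
            for s, e in g.exonic_union:
                self._exon_tree[g.chrom].addi(s, e, g.gene_id)
            for tx in g.transcripts:
                introns = tx.introns
                for j in introns:
                    self.known_junctions.add(j)
                    self._known_coords.add(j.coords)
                    self._strand_by_coords[j.coords] = j.strand
                    self.intron_genes[j.coords].add(g.gene_id)
                    acceptor = j.intron_end if g.strand != "-" else j.intron_start
                    self._acceptors[g.gene_id].add(acceptor)
                for u, d in zip(introns, introns[1:]):
                    self.exon_triples.add((u, d))
                donor = tx.first_exon_donor
                if donor is not None:
                    fe = tx.first_exon
                    self.first_exon_donors[g.gene_id].add(
                        ((fe.chrom, fe.start, fe.end), donor)
                    )

        for j in self.known_junctions:
            self._intron_tree[j.chrom].addi(j.intron_start, j.intron_end, j)
            for pos, side in ((j.intron_start, "L"), (j.intron_end, "R")):
                self._border_introns[(j.chrom, pos)].append((j, side))

        for chrom in self._intron_tree:
            positions = sorted(
                {p for (c, p) in self._border_introns if c == chrom}
            )
            self._borders[chrom] = positions

        # annotated retention: an exon spanning the whole intron
        for g in self.genes.values():
            for tx in g.transcripts:
                for e in tx.exons:
                    for hit in self._intron_tree[g.chrom].overlap(e.start, e.end):
                        j = hit.data
                        if e.start <= j.intron_start and j.intron_end <= e.end:
                            self.retention_known.add(j.coords)

        # AFE donor junctions of genes with >= 2 distinct first exons
        self.afe_donor_coords: set = set()
        for gid, entries in self.first_exon_donors.items():
            if len({fe for fe, _ in entries}) >= 2:
                self.afe_donor_coords.update(j.coords for _, j in entries)

    # -- membership ---------------------------------------------------------

    @property
    def known_introns(self) -> set:
        return self.known_junctions

    def is_known_junction(self, key) -> bool:
        coords = key.coords if isinstance(key, JunctionKey) else tuple(key)
        return coords in self._known_coords

    def junction_strand(self, coords) -> str:
        return self._strand_by_coords.get(tuple(coords), ".")

    # -- spatial queries ----------------------------------------------------

    def genes_overlapping(self, chrom: str, start: int, end: int) -> set:
        return {iv.data for iv in self._gene_tree[chrom].overlap(start, end)}

    def genes_with_exon_overlap(self, chrom: str, start: int, end: int) -> set:
        return {iv.data for iv in self._exon_tree[chrom].overlap(start, end)}

    def exon_intervals_overlapping(self, chrom: str, start: int, end: int) -> list:
        return [(iv.begin, iv.end) for iv in self._exon_tree[chrom].overlap(start, end)]

    def borders_in(self, chrom: str, lo: int, hi: int) -> list:
        """Annotated exon–intron border positions p with lo <= p <= hi."""
        positions = self._borders.get(chrom, [])
        i = bisect.bisect_left(positions, lo)
        out = []
        while i < len(positions) and positions[i] <= hi:
            out.append(positions[i])
            i += 1
        return out

    def introns_at_border(self, chrom: str, pos: int) -> list:
        """[(JunctionKey, 'L'|'R')] for introns having a border at pos."""
        return self._border_introns.get((chrom, pos), [])

    def introns_containing(self, chrom: str, start: int, end: int) -> list:
        out = []
        for iv in self._intron_tree[chrom].overlap(start, end):
            j = iv.data
            if j.intron_start <= start and end <= j.intron_end:
                out.append(j)
        return out

    def acceptors_of(self, gene_id: str) -> set:
        return self._acceptors.get(gene_id, set())

    def in_annotated_exon(self, gene_id: str, pos: int) -> bool:
        g = self.genes[gene_id]
        return any(s <= pos < e for s, e in g.exonic_union)

    # -- export -------------------------------------------------------------

    def to_tsv(self, path) -> None:
        """One junction per row: chrom, intron_start, intron_end, strand, gene_id, known."""
        rows = []
        for j in sorted(self.known_junctions):
            for gid in sorted(self.intron_genes[j.coords]):
                rows.append(
                    (j.chrom, j.intron_start, j.intron_end, j.strand, gid, 1)
                )
        with open(path, "w") as fh:
            fh.write("chrom\tintron_start\tintron_end\tstrand\tgene_id\tknown\n")
            for r in rows:
                fh.write("\t".join(map(str, r)) + "\n")


def build_annotation_index(genes: Iterable) -> AnnotationIndex:
    """Index validated gene models for event detection and novelty labelling."""
    return AnnotationIndex(genes)
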