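"""Read classification and junction/intron-evidence tabulation.

Aligned reads are partitioned into three exclusive evidence groups by their
position relative to annotated splice sites:

* Group 1 (``EXON_EXON``)   — spliced reads whose N gap is anchored by at
  least ``min_overhang`` aligned nt on each side; these count toward junction
  read tables.
* Group 2 (``EXON_INTRON``) — contiguous reads bridging an annotated
  exon–intron border with ``min_overhang`` nt on each side of the border.
* Group 3 (``INTRONIC``)    — contiguous reads fully inside an annotated
  intron; used only for intron-retention coverage and depth, never for
  differential candidates.

Everything else is ``OTHER``.  Gap evidence dominates: a spliced read is
Group 1 even if one of its blocks also touches a border.
"""

from __future__ import annotations

import enum
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd
import pysam

from .annotation import AnnotationIndex, JunctionKey

DEFAULT_MIN_OVERHANG = 6
DEFAULT_MIN_MAPQ = 1

_REF_OPS = {"M", "D", "=", "X"}
_CIGAR_CODES = "MIDNSHP=XB"


class ReadGroup(enum.Enum):
    EXON_EXON = "exon_exon"      # Group 1
    EXON_INTRON = "exon_intron"  # Group 2
    INTRONIC = "intronic"        # Group 3
    OTHER = "other"


@dataclass
class AlignedRead:
    """Minimal alignment record; CIGAR as [(op, length)] with op in MIDNS."""

    read_id: str
    chrom: str
    pos: int  # 0-based leftmost aligned base
    cigar: list
    mapq: int = 60
    sample_id: str = ""

    @classmethod
    def from_pysam(cls, seg: "pysam.AlignedSegment", sample_id: str) -> "AlignedRead":
        cig = [(_CIGAR_CODES[op], ln) for op, ln in seg.cigartuples or []]
        return cls(
            read_id=seg.query_name,
            chrom=seg.reference_name,
            pos=seg.reference_start,
            cigar=cig,
            mapq=seg.mapping_quality,
            sample_id=sample_id,
        )

    def blocks_and_gaps(self) -> tuple:
        """Aligned reference blocks (M/D runs, split by N) and the N gaps.

        Returns ``(blocks, gaps)`` where both are lists of half-open
        ``(start, end)`` reference intervals.  I and S consume no reference.
        """
        blocks, gaps = [], []
        ref = self.pos
        block_start: Optional[int] = None
        for op, ln in self.cigar:
            if op in _REF_OPS:
                if block_start is None:
                    block_start = ref
                ref += ln
            elif op == "N":
                if block_start is not None:
                    blocks.append((block_start, ref))
                    block_start = None
                gaps.append((ref, ref + ln))
                ref += ln
            # I, S, H, P consume no reference
        if block_start is not None:
            blocks.append((block_start, ref))
        return blocks, gaps


def anchored_gaps(read: AlignedRead, min_overhang: int) -> list:
    """Gaps of ``read`` flanked by >= min_overhang aligned nt on each side."""
    blocks, gaps = read.blocks_and_gaps()
    out = []
    for i, gap in enumerate(gaps):
        left = blocks[i][1] - blocks[i][0] if i < len(blocks) else 0
        right = blocks[i + 1][1] - blocks[i + 1][0] if i + 1 < len(blocks) else 0
        if left >= min_overhang and right >= min_overhang:
            out.append(gap)
    return out


def classify_read(
    read: AlignedRead,
    index: AnnotationIndex,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
    extra_introns: Optional[set] = None,
) -> ReadGroup:
    """Assign a read to exactly one of the three evidence groups (or OTHER).

    ``extra_introns`` — additional intron coords (e.g. from observed novel
    junctions) treated as annotated for border/containment checks.
    """
    blocks, gaps = read.blocks_and_gaps()
    if gaps:
        return (
            ReadGroup.EXON_EXON
            if anchored_gaps(read, min_overhang)
            else ReadGroup.OTHER
        )
    if not blocks:
        return ReadGroup.OTHER
    start, end = blocks[0][0], blocks[-1][1]
    borders = _working_borders(index, extra_introns, read.chrom,
                               start + min_overhang, end - min_overhang)
    if borders:
        return ReadGroup.EXON_INTRON
    if _containing_introns(index, extra_introns, read.chrom, start, end):
        return ReadGroup.INTRONIC
    return ReadGroup.OTHER


def _working_borders(index, extra_introns, chrom, lo, hi) -> list:
    if lo > hi:
        return []
    positions = list(index.borders_in(chrom, lo, hi))
    if extra_introns:
        for c, s, e in extra_introns:
            if c == chrom:
                if lo <= s <= hi:
                    positions.append(s)
                if lo <= e <= hi:
                    positions.append(e)
    return positions


def _containing_introns(index, extra_introns, chrom, start, end) -> list:
    """Intron coords containing [start, end) for which the span is genuinely
    intronic: an annotated exon nested inside the intron (a cassette exon
    seen from the skipping isoform's intron) disqualifies that intron, while
    a retention exon spanning the whole intron does not."""
    containers = [j.coords for j in index.introns_containing(chrom, start, end)]
    if extra_introns:
        for c, s, e in extra_introns:
            if c == chrom and s <= start and end <= e:
                containers.append((c, s, e))
    if not containers:
        return []
    exon_ivs = index.exon_intervals_overlapping(chrom, start, end)
    out = []
    for coords in containers:
        _, s, e = coords
        if any(s <= xs and xe <= e for xs, xe in exon_ivs):
            continue
        out.append(coords)
    return out


# ---------------------------------------------------------------------------
# Junction counts


class JunctionCounts:
    """Per-sample read counts keyed by junction coords (chrom, start, end).

    Strand is tracked separately per junction and defaults to unknown until
    :meth:`resolve_strands` assigns it from the unique overlapping gene.
    """

    def __init__(self, min_overhang: int = DEFAULT_MIN_OVERHANG):
        self.min_overhang = min_overhang
        self._counts: dict = defaultdict(Counter)  # sample -> Counter[coords]
        self.strand: dict = {}  # coords -> strand

    # -- mutation -----------------------------------------------------------

    def add(self, coords: tuple, sample_id: str, n: int = 1, strand: str = ".") -> None:
        if n < 0:
            raise ValueError("negative junction count")
        self._counts[sample_id][tuple(coords)] += n
        cur = self.strand.get(tuple(coords), ".")
        if cur == ".":
            self.strand[tuple(coords)] = strand

    def merge(self, other: "JunctionCounts") -> "JunctionCounts":
        for sample, ctr in other._counts.items():
            for coords, n in ctr.items():
                self.add(coords, sample, n, other.strand.get(coords, "."))
        return self

    def resolve_strands(self, index: AnnotationIndex) -> None:
        """Assign unknown strands from annotation or unique gene overlap."""
        for coords in self.keys():
            if self.strand.get(coords, ".") != ".":
                continue
            ann = index.junction_strand(coords)
            if ann != ".":
                self.strand[coords] = ann
                continue
            chrom, s, e = coords
            genes = index.genes_overlapping(chrom, s, e)
            if len(genes) == 1:
                self.strand[coords] = index.genes[next(iter(genes))].strand

    # -- access -------------------------------------------------------------

    @property
    def samples(self) -> list:
        return sorted(self._counts)

    def keys(self) -> list:
        allkeys = set()
        for ctr in self._counts.values():
            allkeys.update(ctr)
        return sorted(allkeys)

    def get(self, coords: tuple, sample_id: str) -> int:
        return self._counts.get(sample_id, Counter()).get(tuple(coords), 0)

    def total(self, coords: tuple) -> int:
        return sum(ctr.get(tuple(coords), 0) for ctr in self._counts.values())

    def key(self, coords: tuple) -> JunctionKey:
        chrom, s, e = coords
        return JunctionKey(chrom, s, e, self.strand.get(tuple(coords), "."))

    # -- I/O ----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        samples = self.samples
        rows = []
        for coords in self.keys():
            chrom, s, e = coords
            row = {
                "chrom": chrom,
                "intron_start": s,
                "intron_end": e,
                "strand": self.strand.get(coords, "."),
            }
            for sm in samples:
                row[sm] = self.get(coords, sm)
            rows.append(row)
        cols = ["chrom", "intron_start", "intron_end", "strand"] + samples
        return pd.DataFrame(rows, columns=cols)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "JunctionCounts":
        df = pd.read_csv(path, sep="\t")
        jc = cls()
        meta = {"chrom", "intron_start", "intron_end", "strand"}
        samples = [c for c in df.columns if c not in meta]
        for rec in df.itertuples(index=False):
            coords = (rec.chrom, int(rec.intron_start), int(rec.intron_end))
            for sm in samples:
                jc.add(coords, sm, int(getattr(rec, sm)), rec.strand)
        return jc


def extract_junction_counts(
    reads: Iterable[AlignedRead],
    min_overhang: int = DEFAULT_MIN_OVERHANG,
) -> JunctionCounts:
    """Tabulate junction read counts; one increment per anchored (read, gap)."""
    jc = JunctionCounts(min_overhang=min_overhang)
    for read in reads:
        for gap in anchored_gaps(read, min_overhang):
            jc.add((read.chrom, gap[0], gap[1]), read.sample_id)
    return jc


def read_sj_tab(path, sample_id: str) -> JunctionCounts:
    """Read a STAR SJ.out.tab junction table (unique-mapping counts).

    Columns: chrom, 1-based intron start, 1-based inclusive intron end,
    strand code (0 unknown / 1 + / 2 −), motif, annotated, unique count,
    multi count, max overhang.
    """
    strand_codes = {"0": ".", "1": "+", "2": "-"}
    jc = JunctionCounts()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 9:
                raise ValueError(
                    f"{path}: line {lineno}: expected 9 columns, got {len(fields)}"
                )
            chrom, start, end, code = fields[0], int(fields[1]), int(fields[2]), fields[3]
            unique = int(fields[6])
            jc.add((chrom, start - 1, end), sample_id, unique,
                   strand_codes.get(code, "."))
    return jc


# ---------------------------------------------------------------------------
# Intron evidence


@dataclass
class IntronEvidenceRecord:
    left_boundary_count: int = 0
    right_boundary_count: int = 0
    intronic_read_count: int = 0
    mean_depth: float = 0.0
    covered_fraction: float = 0.0


class EvidenceTable:
    """Per (intron coords, sample) boundary/intronic evidence."""

    def __init__(self):
        self._records: dict = {}
        self.strand: dict = {}

    def record(self, coords: tuple, sample_id: str) -> IntronEvidenceRecord:
        key = (tuple(coords), sample_id)
        if key not in self._records:
            self._records[key] = IntronEvidenceRecord()
        return self._records[key]

    def get(self, coords: tuple, sample_id: str) -> IntronEvidenceRecord:
        return self._records.get((tuple(coords), sample_id), IntronEvidenceRecord())

    def keys(self) -> list:
        return sorted({coords for coords, _ in self._records})

    @property
    def samples(self) -> list:
        return sorted({sm for _, sm in self._records})

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (coords, sm), rec in sorted(self._records.items()):
            chrom, s, e = coords
            rows.append(
                {
                    "chrom": chrom,
                    "intron_start": s,
                    "intron_end": e,
                    "strand": self.strand.get(coords, "."),
                    "sample": sm,
                    "left_boundary_count": rec.left_boundary_count,
                    "right_boundary_count": rec.right_boundary_count,
                    "intronic_read_count": rec.intronic_read_count,
                    "mean_depth": round(rec.mean_depth, 6),
                    "covered_fraction": round(rec.covered_fraction, 6),
                }
            )
        cols = [
            "chrom", "intron_start", "intron_end", "strand", "sample",
            "left_boundary_count", "right_boundary_count",
            "intronic_read_count", "mean_depth", "covered_fraction",
        ]
        return pd.DataFrame(rows, columns=cols)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "EvidenceTable":
        df = pd.read_csv(path, sep="\t")
        ev = cls()
        for rec in df.itertuples(index=False):
            coords = (rec.chrom, int(rec.intron_start), int(rec.intron_end))
            r = ev.record(coords, rec.sample)
            r.left_boundary_count = int(rec.left_boundary_count)
            r.right_boundary_count = int(rec.right_boundary_count)
            r.intronic_read_count = int(rec.intronic_read_count)
            r.mean_depth = float(rec.mean_depth)
            r.covered_fraction = float(rec.covered_fraction)
            ev.strand[coords] = rec.strand
        return ev


def collect_intron_evidence(
    reads: Iterable[AlignedRead],
    index: AnnotationIndex,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
    extra_introns: Optional[set] = None,
) -> EvidenceTable:
    """Accumulate Group 2 boundary counts and Group 3 coverage per intron.

    Depth and covered fraction are computed over intronic bases from INTRONIC
    reads only; boundary reads contribute border counts, not depth.
    """
    extra = {tuple(c) for c in extra_introns} if extra_introns else set()
    working = {j.coords: j.strand for j in index.known_junctions}
    for c in extra:
        working.setdefault(c, ".")
    by_border: dict = defaultdict(list)  # (chrom, pos) -> [(coords, side)]
    for coords in working:
        chrom, s, e = coords
        by_border[(chrom, s)].append((coords, "L"))
        by_border[(chrom, e)].append((coords, "R"))

    ev = EvidenceTable()
    for coords, strand in working.items():
        ev.strand[coords] = strand
    coverage: dict = {}  # (coords, sample) -> np.ndarray

    for read in reads:
        group = classify_read(read, index, min_overhang, extra)
        if group is ReadGroup.EXON_INTRON:
            blocks, _ = read.blocks_and_gaps()
            start, end = blocks[0][0], blocks[-1][1]
            positions = _working_borders(
                index, extra, read.chrom, start + min_overhang, end - min_overhang
            )
            for pos in set(positions):
                for coords, side in by_border.get((read.chrom, pos), []):
                    rec = ev.record(coords, read.sample_id)
                    if side == "L":
                        rec.left_boundary_count += 1
                    else:
                        rec.right_boundary_count += 1
        elif group is ReadGroup.INTRONIC:
            blocks, _ = read.blocks_and_gaps()
            start, end = blocks[0][0], blocks[-1][1]
            containers = _containing_introns(
                index, extra, read.chrom, start, end
            )
            for coords in set(containers):
                rec = ev.record(coords, read.sample_id)
                rec.intronic_read_count += 1
                key = (coords, read.sample_id)
                if key not in coverage:
                    coverage[key] = np.zeros(coords[2] - coords[1], dtype=np.int32)
                cov = coverage[key]
                for bs, be in blocks:
                    lo = max(bs, coords[1]) - coords[1]
                    hi = min(be, coords[2]) - coords[1]
                    if hi > lo:
                        cov[lo:hi] += 1

    for (coords, sample), cov in coverage.items():
        rec = ev.record(coords, sample)
        rec.mean_depth = float(cov.mean())
        rec.covered_fraction = float((cov > 0).mean())
    return ev


# ---------------------------------------------------------------------------
# SAM ingestion


def iter_sam(
    path,
    sample_id: str,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> Iterator[AlignedRead]:
    """Yield mapped, quality-filtered reads from SAM/BAM."""
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped or seg.is_secondary or seg.is_supplementary:
                continue
            if seg.mapping_quality < min_mapq:
                continue
            yield AlignedRead.from_pysam(seg, sample_id)


def tabulate_sample(
    path,
    index: AnnotationIndex,
    sample_id: str,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    extra_introns: Optional[set] = None,
) -> tuple:
    """One pass over an alignment file: junction counts, intron evidence,
    per-gene exonic read counts, and a ReadGroup tally.

    Gene counting drops reads whose blocks overlap exons of more than one
    gene (ambiguous) and reads with no exonic overlap.
    """
    reads = list(iter_sam(path, sample_id, min_mapq))
    jc = extract_junction_counts(reads, min_overhang)
    jc.resolve_strands(index)
    if extra_introns is None:
        extra_introns = {
            coords for coords in jc.keys() if not index.is_known_junction(coords)
        }
    ev = collect_intron_evidence(reads, index, min_overhang, extra_introns)
    tally = Counter()
    gene_counts: Counter = Counter()
    for read in reads:
        tally[classify_read(read, index, min_overhang, extra_introns)] += 1
        blocks, _ = read.blocks_and_gaps()
        genes = set()
        for bs, be in blocks:
            genes |= index.genes_with_exon_overlap(read.chrom, bs, be)
        if len(genes) == 1:
            gene_counts[next(iter(genes))] += 1
    return jc, ev, gene_counts, tally
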