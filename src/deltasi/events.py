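"""Candidate alternative-splicing event enumeration and novelty labelling.

Five event classes are modelled, matching the usual junction-level taxonomy:
intron retention (IR), exon skipping (ES), alternative first exon (AFE), and
alternative 5'/3' splice sites (A5SS/A3SS).  Events are built from the union
of observed and annotated junctions, so novel variants (unannotated skip
junctions, retention states, first exons, donors/acceptors) are detectable;
each event is labelled ``novel`` when any defining evidence key — or, for IR,
the retention state itself — is absent from the annotation.

Evidence keys inside ``variant_form`` / ``canonical_form`` are junction
coords tuples ``(chrom, start, end)`` or boundary keys ``("bL"|"bR", coords)``
for the two exon–intron borders of a retained intron.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .annotation import AnnotationIndex, JunctionKey
from .junctions import EvidenceTable, JunctionCounts

MAX_MIDDLE_EXON = 10_000  # guard against chimera-like skip triples


class EventType(enum.Enum):
    INTRON_RETENTION = "IR"
    EXON_SKIPPING = "ES"
    ALT_FIRST_EXON = "AFE"
    ALT_5SS = "A5SS"
    ALT_3SS = "A3SS"


@dataclass
class CandidateEvent:
    event_id: str
    etype: EventType
    gene_id: Optional[str]
    chrom: str
    strand: str
    variant_form: frozenset
    canonical_form: frozenset
    novel: bool
    ambiguous: bool = False
    # type-specific evidence handles used for SI support
    intron: Optional[tuple] = None          # IR
    skip: Optional[tuple] = None            # ES: skip junction
    upstream: Optional[tuple] = None        # ES: flanking junctions
    downstream: Optional[tuple] = None
    variant_j: Optional[tuple] = None       # A5SS/A3SS/AFE: variant junction
    canonical_j: Optional[tuple] = None     # A5SS/A3SS
    other_donors: tuple = field(default_factory=tuple)  # AFE

    def __post_init__(self) -> None:
        if self.variant_form & self.canonical_form:
            raise ValueError(f"{self.event_id}: overlapping variant/canonical forms")


# ---------------------------------------------------------------------------
# Deterministic event ids


def _span(coords: tuple) -> str:
    return f"{coords[1]}-{coords[2]}"


def ir_event_id(coords: tuple) -> str:
    return f"IR@{coords[0]}:{_span(coords)}"


def es_event_id(skip: tuple, u: tuple, d: tuple) -> str:
    return f"ES@{skip[0]}:{_span(skip)}^{u[2]}-{d[1]}"


def alt_ss_event_id(side: str, variant: tuple, canonical: tuple) -> str:
    tag = "A5" if side == "5SS" else "A3"
    return f"{tag}@{variant[0]}:{_span(variant)}>{_span(canonical)}"


def afe_event_id(gene_id: str, donor: tuple) -> str:
    return f"AFE@{donor[0]}:{_span(donor)}:{gene_id}"


# ---------------------------------------------------------------------------
# Helpers


def _assign_gene(index: AnnotationIndex, chrom: str, intervals: Iterable) -> tuple:
    """Unique gene overlapping all evidence intervals; (gene_id, ambiguous)."""
    common: Optional[set] = None
    for s, e in intervals:
        hits = index.genes_overlapping(chrom, s, e)
        common = hits if common is None else common & hits
    if not common:
        return None, True
    if len(common) > 1:
        return None, True
    return next(iter(common)), False


def label_novel(
    variant_form: Iterable, canonical_form: Iterable, index: AnnotationIndex
) -> bool:
    """True iff any defining junction key is absent from the annotation.

    Boundary keys carry the intron coords; their junction-novelty follows the
    intron interval.  The IR retention-state rule is applied by the IR
    detector on top of this.
    """
    for key in list(variant_form) + list(canonical_form):
        coords = key[1] if isinstance(key[0], str) and key[0] in ("bL", "bR") else key
        if not index.is_known_junction(coords):
            return True
    return False


def _observed_coords(junctions: JunctionCounts) -> set:
    return {c for c in junctions.keys() if junctions.total(c) > 0}


# ---------------------------------------------------------------------------
# Detectors


def detect_intron_retention(
    junctions: JunctionCounts,
    evidence: EvidenceTable,
    index: AnnotationIndex,
) -> list:
    """One IR event per intron with spliced-junction or boundary evidence.

    The intron universe is the annotated introns plus intervals of observed
    novel junctions.  An IR event is *known* only when some annotated
    transcript retains the intron inside an exon; otherwise it is novel even
    on an annotated intron.
    """
    universe: dict = {}  # coords -> strand
    for j in index.known_junctions:
        universe[j.coords] = j.strand
    for coords in _observed_coords(junctions):
        if coords not in universe:
            universe[coords] = junctions.strand.get(coords, ".")

    samples = set(junctions.samples) | set(evidence.samples)
    events = []
    for coords in sorted(universe):
        spliced = junctions.total(coords)
        boundary = sum(
            evidence.get(coords, sm).left_boundary_count
            + evidence.get(coords, sm).right_boundary_count
            for sm in samples
        )
        if spliced <= 0 and boundary <= 0:
            continue
        chrom = coords[0]
        gene_ids = index.intron_genes.get(coords)
        if gene_ids:
            gene_id = sorted(gene_ids)[0] if len(gene_ids) == 1 else None
            ambiguous = len(gene_ids) > 1
        else:
            gene_id, ambiguous = _assign_gene(
                index, chrom, [(coords[1], coords[2])]
            )
        novel = (not index.is_known_junction(coords)) or (
            coords not in index.retention_known
        )
        events.append(
            CandidateEvent(
                event_id=ir_event_id(coords),
                etype=EventType.INTRON_RETENTION,
                gene_id=gene_id,
                chrom=chrom,
                strand=universe[coords],
                variant_form=frozenset({("bL", coords), ("bR", coords)}),
                canonical_form=frozenset({coords}),
                novel=novel,
                ambiguous=ambiguous,
                intron=coords,
            )
        )
    return events


def detect_exon_skipping(
    junctions: JunctionCounts,
    index: AnnotationIndex,
    max_middle_exon: int = MAX_MIDDLE_EXON,
) -> list:
    """Cassette-exon events from junction triples (u, d, skip).

    The skip junction shares its start with u and its end with d; the middle
    exon is [u.end, d.start) taken from junction geometry, so novel cassette
    exons are detectable.  Each of u, d, skip must be observed or annotated.
    """
    pool = _observed_coords(junctions) | {j.coords for j in index.known_junctions}
    by_start: dict = {}
    by_end: dict = {}
    for c in pool:
        by_start.setdefault((c[0], c[1]), []).append(c)
        by_end.setdefault((c[0], c[2]), []).append(c)
    annotated_pairs = {
        (u.coords, d.coords) for u, d in index.exon_triples
    }

    events = []
    for skip in sorted(pool):
        chrom = skip[0]
        candidates = []
        for u in by_start.get((chrom, skip[1]), []):
            if u == skip:
                continue
            for d in by_end.get((chrom, skip[2]), []):
                if d == skip or d == u:
                    continue
                middle = d[1] - u[2]
                if middle <= 0 or middle > max_middle_exon:
                    continue
                candidates.append((u, d))
        if not candidates:
            continue
        annotated = [p for p in candidates if p in annotated_pairs]
        if annotated:
            u, d = min(annotated)
        else:
            u, d = max(
                candidates,
                key=lambda p: (
                    junctions.total(p[0]) + junctions.total(p[1]),
                    -p[0][2],
                ),
            )
        gene_id, ambiguous = _assign_gene(
            index, chrom, [(skip[1], skip[2])]
        )
        strand = (
            index.junction_strand(skip)
            if index.is_known_junction(skip)
            else junctions.strand.get(skip, ".")
        )
        events.append(
            CandidateEvent(
                event_id=es_event_id(skip, u, d),
                etype=EventType.EXON_SKIPPING,
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                variant_form=frozenset({skip}),
                canonical_form=frozenset({u, d}),
                novel=label_novel({skip}, {u, d}, index),
                ambiguous=ambiguous,
                skip=skip,
                upstream=u,
                downstream=d,
            )
        )
    return events


def _strand_of(coords: tuple, junctions: JunctionCounts, index: AnnotationIndex) -> str:
    if index.is_known_junction(coords):
        return index.junction_strand(coords)
    return junctions.strand.get(coords, ".")


def detect_alt_ss(
    junctions: JunctionCounts,
    index: AnnotationIndex,
    side: str,
    control_sample: Optional[str] = None,
    exclude_coords: Optional[set] = None,
) -> list:
    """Competing donors sharing an acceptor (5SS) or vice versa (3SS).

    Strand-aware: on + the donor is the intron start and the acceptor the
    intron end; on − they swap.  The canonical junction is the annotated one;
    if zero or several are annotated, the junction with the higher count in
    the control sample wins, ties going to the longer intron.  Strandless
    junctions are skipped.  ``exclude_coords`` removes first-exon donor
    junctions already claimed by AFE events.
    """
    if side not in ("5SS", "3SS"):
        raise ValueError(f"side must be 5SS or 3SS, got {side!r}")
    pool = _observed_coords(junctions) | {j.coords for j in index.known_junctions}
    if exclude_coords:
        pool -= set(exclude_coords)

    groups: dict = {}
    skipped_strandless = 0
    for c in sorted(pool):
        strand = _strand_of(c, junctions, index)
        if strand == ".":
            skipped_strandless += 1
            continue
        # shared end: 5SS shares the acceptor, 3SS shares the donor
        if (side == "5SS") == (strand == "+"):
            shared = ("end", c[0], strand, c[2])
        else:
            shared = ("start", c[0], strand, c[1])
        groups.setdefault(shared, []).append(c)

    def control_count(c):
        if control_sample is not None:
            return junctions.get(c, control_sample)
        return junctions.total(c)

    events = []
    for shared in sorted(groups):
        members = groups[shared]
        if len(members) < 2:
            continue
        annotated = [c for c in members if index.is_known_junction(c)]
        if len(annotated) == 1:
            canonical = annotated[0]
        else:
            canonical = max(
                members, key=lambda c: (control_count(c), c[2] - c[1], c)
            )
        strand = shared[2]
        for variant in sorted(members):
            if variant == canonical:
                continue
            gene_id, ambiguous = _assign_gene(
                index,
                variant[0],
                [(variant[1], variant[2]), (canonical[1], canonical[2])],
            )
            etype = EventType.ALT_5SS if side == "5SS" else EventType.ALT_3SS
            events.append(
                CandidateEvent(
                    event_id=alt_ss_event_id(side, variant, canonical),
                    etype=etype,
                    gene_id=gene_id,
                    chrom=variant[0],
                    strand=strand,
                    variant_form=frozenset({variant}),
                    canonical_form=frozenset({canonical}),
                    novel=label_novel({variant}, {canonical}, index),
                    ambiguous=ambiguous,
                    variant_j=variant,
                    canonical_j=canonical,
                )
            )
    return events


def find_afe_donors(
    junctions: JunctionCounts, index: AnnotationIndex
) -> dict:
    """Per gene: set of first-exon donor junction coords (annotated + novel).

    A novel first-exon donor is an observed unannotated junction whose
    acceptor end matches the acceptor used by an annotated first-exon donor
    of the gene (so it competes at the same internal acceptor) while its
    donor end lies outside every annotated exon of the gene (a novel first
    exon).  Requiring the first-exon acceptor, not just any annotated
    acceptor, keeps novel donors at internal introns classified as
    alternative 5'/3' splice-site variants instead.
    """
    donors: dict = {}
    fe_acceptors: dict = {}
    for gid, entries in index.first_exon_donors.items():
        donors[gid] = {j.coords for _, j in entries}
        gene = index.genes[gid]
        fe_acceptors[gid] = {
            (j.intron_start if gene.strand == "-" else j.intron_end)
            for _, j in entries
        }
    for coords in _observed_coords(junctions):
        if index.is_known_junction(coords):
            continue
        chrom, s, e = coords
        for gid in sorted(index.genes_overlapping(chrom, s, e)):
            gene = index.genes[gid]
            if gene.strand == "-":
                acceptor = s
                donor_pos = e - 1
            else:
                acceptor = e
                donor_pos = s
            if acceptor not in fe_acceptors.get(gid, set()):
                continue
            if index.in_annotated_exon(gid, donor_pos):
                continue
            donors.setdefault(gid, set()).add(coords)
    return donors


def detect_alt_first_exon(
    junctions: JunctionCounts, index: AnnotationIndex
) -> list:
    """Per gene with >= 2 first-exon donor junctions: one event per donor.

    The event's variant form is that donor junction; its canonical form is
    the gene's other first-exon donors pooled.  Novelty follows the variant
    donor alone: a gene acquiring one novel first exon does not turn its
    annotated first-exon events novel merely because the newcomer joins
    their canonical pools.
    """
    events = []
    donors = find_afe_donors(junctions, index)
    for gid in sorted(donors):
        ds = sorted(donors[gid])
        if len(ds) < 2:
            continue
        gene = index.genes[gid]
        for donor in ds:
            others = tuple(c for c in ds if c != donor)
            events.append(
                CandidateEvent(
                    event_id=afe_event_id(gid, donor),
                    etype=EventType.ALT_FIRST_EXON,
                    gene_id=gid,
                    chrom=gene.chrom,
                    strand=gene.strand,
                    variant_form=frozenset({donor}),
                    canonical_form=frozenset(others),
                    novel=not index.is_known_junction(donor),
                    ambiguous=False,
                    variant_j=donor,
                    other_donors=others,
                )
            )
    return events


def detect_events(
    junctions: JunctionCounts,
    evidence: EvidenceTable,
    index: AnnotationIndex,
    control_sample: Optional[str] = None,
    max_middle_exon: int = MAX_MIDDLE_EXON,
) -> list:
    """All candidate events of the five classes, deterministically ordered."""
    afe = detect_alt_first_exon(junctions, index)
    afe_coords = {e.variant_j for e in afe}
    events = (
        detect_intron_retention(junctions, evidence, index)
        + detect_exon_skipping(junctions, index, max_middle_exon)
        + afe
        + detect_alt_ss(junctions, index, "5SS", control_sample, afe_coords)
        + detect_alt_ss(junctions, index, "3SS", control_sample, afe_coords)
    )
    events.sort(key=lambda e: (e.etype.value, e.chrom, e.event_id))
    seen = set()
    unique = []
    for e in events:
        sig = (e.etype, e.variant_form)
        if sig in seen:
            continue
        seen.add(sig)
        unique.append(e)
    return unique


def events_to_frame(events: Iterable) -> "pd.DataFrame":
    import pandas as pd

    def fmt(form):
        parts = []
        for key in sorted(form, key=str):
            if isinstance(key[0], str) and key[0] in ("bL", "bR"):
                side, coords = key
                parts.append(f"{side}:{coords[0]}:{coords[1]}-{coords[2]}")
            else:
                parts.append(f"J:{key[0]}:{key[1]}-{key[2]}")
        return ",".join(parts)

    rows = [
        {
            "event_id": e.event_id,
            "type": e.etype.value,
            "gene_id": e.gene_id if e.gene_id else "",
            "chrom": e.chrom,
            "strand": e.strand,
            "variant_form": fmt(e.variant_form),
            "canonical_form": fmt(e.canonical_form),
            "novel": int(e.novel),
            "ambiguous": int(e.ambiguous),
        }
        for e in events
    ]
    cols = [
        "event_id", "type", "gene_id", "chrom", "strand",
        "variant_form", "canonical_form", "novel", "ambiguous",
    ]
    return pd.DataFrame(rows, columns=cols)
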