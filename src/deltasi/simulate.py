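"""Synthetic annotation, ground-truth events, count tables and alignments.

The generator emulates the data regime the pipeline targets: a small number
of deeply sequenced libraries (one per condition — a normoxia control plus
acute and chronic treatment phases, n = 1 each), multi-isoform gene models,
and per-event isoform proportions (SI) that shift between conditions for a
planned set of events of all five splicing classes.  Junction, exon–intron
boundary and intronic read evidence are drawn with Poisson (optionally
negative-binomial) noise around expectations fixed by the true SI, and can
be realised read-by-read into valid SAM so the extraction stage is
exercisable end to end.  Everything is driven by one ``numpy`` Generator, so
a fixed seed gives byte-identical outputs.

Default scale is a desk-size fixture: 200 genes, 60 true events with
ΔSI_true ∈ {0, ±0.2, ±0.4}, 200 informative reads per event and sample,
80 nt single-end reads.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import pysam

from .annotation import (
    GeneModel,
    GenomicInterval,
    Transcript,
    write_gtf,
)
from .events import (
    EventType,
    afe_event_id,
    alt_ss_event_id,
    es_event_id,
    ir_event_id,
)
from .junctions import EvidenceTable, JunctionCounts


class ConfigurationError(ValueError):
    pass


@dataclass
class PlannedEvent:
    """One true splicing event: class, effect size and affected phases."""

    etype: EventType
    delta_si: float
    baseline_si: float
    phases: Tuple[str, ...]  # treated conditions where the shift applies

    def __post_init__(self) -> None:
        lo = min(self.baseline_si, self.baseline_si + self.delta_si)
        hi = max(self.baseline_si, self.baseline_si + self.delta_si)
        if lo < 0 or hi > 1:
            raise ConfigurationError(
                f"baseline {self.baseline_si} + delta {self.delta_si} leaves [0,1]"
            )


def _default_baseline(etype: EventType, delta: float) -> float:
    # Alt-SS events keep the canonical junction in the majority in the
    # control so the count-based canonical choice is stable.
    if delta >= 0:
        return 0.3
    if etype in (EventType.ALT_5SS, EventType.ALT_3SS):
        return 0.4
    return 0.5


def default_event_plan(
    n_events: int = 60,
    deltas: Tuple[float, ...] = (0.0, 0.2, -0.2, 0.4, -0.4),
    type_quotas: Optional[Dict[EventType, int]] = None,
    conditions: Tuple[str, ...] = ("normoxia", "acute", "chronic"),
    control: str = "normoxia",
) -> List[PlannedEvent]:
    """Mixed-type plan with effects split across the treated phases."""
    if type_quotas is None:
        type_quotas = {
            EventType.INTRON_RETENTION: int(round(n_events * 0.4)),
            EventType.EXON_SKIPPING: int(round(n_events * 0.2)),
            EventType.ALT_5SS: int(round(n_events * 0.15)),
            EventType.ALT_3SS: int(round(n_events * 0.15)),
            EventType.ALT_FIRST_EXON: 0,
        }
        type_quotas[EventType.ALT_FIRST_EXON] = n_events - sum(type_quotas.values())
    treated = [c for c in conditions if c != control]
    phase_cycle = [tuple(treated)] + [(t,) for t in treated]
    plan: List[PlannedEvent] = []
    i = 0
    for etype in EventType:
        for _ in range(type_quotas.get(etype, 0)):
            delta = deltas[i % len(deltas)]
            plan.append(
                PlannedEvent(
                    etype=etype,
                    delta_si=delta,
                    baseline_si=_default_baseline(etype, delta),
                    phases=phase_cycle[i % len(phase_cycle)],
                )
            )
            i += 1
    return plan


@dataclass
class SimulationConfig:
    n_genes: int = 200
    exons_per_transcript: Tuple[int, int] = (4, 8)
    exon_len: Tuple[int, int] = (100, 300)
    intron_len: Tuple[int, int] = (200, 1000)
    conditions: Tuple[str, ...] = ("normoxia", "acute", "chronic")
    control: str = "normoxia"
    expression_log_mean: float = 5.0  # ln-scale; median ~150 exonic reads
    expression_log_sigma: float = 0.6
    depth: float = 200.0  # expected informative reads per event and sample
    background_depth: float = 50.0  # expected reads on non-event junctions
    noise: str = "poisson"  # or "nb"
    nb_dispersion: float = 0.05
    novel_fraction: float = 0.75
    de_up_fraction: float = 0.10
    de_down_fraction: float = 0.05
    fold_up_range: Tuple[float, float] = (1.6, 4.0)
    fold_down_range: Tuple[float, float] = (0.25, 0.625)
    read_len: int = 80
    anchor: int = 40  # aligned nt on each side of a simulated gap/border
    gene_gap: int = 10_000
    chrom: str = "chrS"
    event_plan: Optional[List[PlannedEvent]] = None

    def __post_init__(self) -> None:
        for name in ("exons_per_transcript", "exon_len", "intron_len"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ConfigurationError(f"bad range for {name}: ({lo}, {hi})")
        if self.exons_per_transcript[0] < 2:
            raise ConfigurationError("transcripts need >= 2 exons to host events")
        if self.control not in self.conditions:
            raise ConfigurationError("control must be one of conditions")
        if self.noise not in ("poisson", "nb"):
            raise ConfigurationError(f"unknown noise model {self.noise!r}")
        if not 0 <= self.novel_fraction <= 1:
            raise ConfigurationError("novel_fraction must lie in [0,1]")
        if self.event_plan is None:
            # 60 events at the default 200 genes; scale down with n_genes
            n_events = max(1, min(60, (self.n_genes * 3) // 10))
            self.event_plan = default_event_plan(
                n_events=n_events, conditions=self.conditions, control=self.control
            )


@dataclass
class TrueEvent:
    event_id: str
    etype: EventType
    gene_id: str
    novel: bool
    si_true: Dict[str, float]  # condition -> SI
    keys: Dict[str, tuple] = field(default_factory=dict)

    def delta(self, treated: str, control: str) -> float:
        return self.si_true[treated] - self.si_true[control]


@dataclass
class GroundTruth:
    events: List[TrueEvent]
    expression: Dict[str, float]  # gene -> base expected exonic reads
    fold_change: Dict[str, Dict[str, float]]  # gene -> condition -> true fold
    conditions: Tuple[str, ...] = ()
    control: str = ""


# ---------------------------------------------------------------------------
# Annotation synthesis


def _draw_gene(
    cfg: SimulationConfig, rng: np.random.Generator, gene_idx: int, cursor: int
) -> Tuple[GeneModel, int]:
    strand = "+" if gene_idx % 2 == 0 else "-"
    n_ex = int(rng.integers(cfg.exons_per_transcript[0], cfg.exons_per_transcript[1] + 1))
    exons = []
    pos = cursor
    for k in range(n_ex):
        elen = int(rng.integers(cfg.exon_len[0], cfg.exon_len[1] + 1))
        exons.append(GenomicInterval(cfg.chrom, pos, pos + elen, strand))
        pos += elen
        if k < n_ex - 1:
            pos += int(rng.integers(cfg.intron_len[0], cfg.intron_len[1] + 1))
    gid = f"G{gene_idx:04d}"
    tx = Transcript(f"{gid}.t1", gid, strand, exons)
    gene = GeneModel(gid, gid, strand, cfg.chrom, [tx])
    return gene, pos + cfg.gene_gap


def _host_capacity(gene: GeneModel, etype: EventType, used_introns: set) -> Optional[dict]:
    """Structural slot for an event on this gene, or None."""
    tx = gene.transcripts[0]
    exons = tx.exons
    n_ex = len(exons)
    n_introns = n_ex - 1
    if etype is EventType.INTRON_RETENTION:
        for k in range(n_introns):
            if k not in used_introns:
                return {"intron_idx": k}
        return None
    if used_introns:
        return None  # non-IR types take a fresh gene
    if etype is EventType.EXON_SKIPPING:
        if n_ex < 3:
            return None
        return {"middle_idx": 1 + (n_ex // 2 - 1) % (n_ex - 2)}
    if etype in (EventType.ALT_5SS, EventType.ALT_3SS):
        return {"intron_idx": n_introns // 2}
    if etype is EventType.ALT_FIRST_EXON:
        # alternative first exon sits inside the transcript's first intron
        first_intron = (
            tx.introns[-1] if gene.strand == "-" else tx.introns[0]
        )
        if first_intron.length < 190:
            return None
        return {}
    return None


_SS_SHIFT = 60  # nt offset of the variant donor/acceptor


def _build_event_structure(
    gene: GeneModel, etype: EventType, slot: dict, novel: bool
) -> Tuple[Dict[str, tuple], Optional[Transcript], str]:
    """Evidence coords, the alternative transcript (annotated iff known),
    and the deterministic event id the detector will assign."""
    tx = gene.transcripts[0]
    exons = tx.exons
    chrom, strand = gene.chrom, gene.strand
    gid = gene.gene_id

    def jc(a: GenomicInterval, b: GenomicInterval) -> tuple:
        return (chrom, a.end, b.start)

    if etype is EventType.INTRON_RETENTION:
        k = slot["intron_idx"]
        intron = jc(exons[k], exons[k + 1])
        merged = GenomicInterval(chrom, exons[k].start, exons[k + 1].end, strand)
        alt_exons = exons[:k] + [merged] + exons[k + 2 :]
        alt = Transcript(f"{gid}.tIR", gid, strand, alt_exons)
        return {"intron": intron}, alt, ir_event_id(intron)

    if etype is EventType.EXON_SKIPPING:
        k = slot["middle_idx"]
        u = jc(exons[k - 1], exons[k])
        d = jc(exons[k], exons[k + 1])
        skip = (chrom, exons[k - 1].end, exons[k + 1].start)
        alt_exons = exons[:k] + exons[k + 1 :]
        alt = Transcript(f"{gid}.tES", gid, strand, alt_exons)
        return {"skip": skip, "u": u, "d": d}, alt, es_event_id(skip, u, d)

    if etype in (EventType.ALT_5SS, EventType.ALT_3SS):
        k = slot["intron_idx"]
        canonical = jc(exons[k], exons[k + 1])
        # the donor side is the intron start on + and the intron end on −;
        # a 5SS shift moves the donor, a 3SS shift moves the acceptor.
        move_start = (etype is EventType.ALT_5SS) == (strand == "+")
        if move_start:
            variant = (chrom, canonical[1] + _SS_SHIFT, canonical[2])
            new_exon = GenomicInterval(
                chrom, exons[k].start, exons[k].end + _SS_SHIFT, strand
            )
            alt_exons = exons[:k] + [new_exon] + exons[k + 1 :]
        else:
            variant = (chrom, canonical[1], canonical[2] - _SS_SHIFT)
            new_exon = GenomicInterval(
                chrom, exons[k + 1].start - _SS_SHIFT, exons[k + 1].end, strand
            )
            alt_exons = exons[: k + 1] + [new_exon] + exons[k + 2 :]
        alt = Transcript(f"{gid}.tSS", gid, strand, alt_exons)
        side = "5SS" if etype is EventType.ALT_5SS else "3SS"
        return (
            {"variant": variant, "canonical": canonical},
            alt,
            alt_ss_event_id(side, variant, canonical),
        )

    if etype is EventType.ALT_FIRST_EXON:
        if strand == "-":
            first_intron = tx.introns[-1]
            alt_e = GenomicInterval(
                chrom, first_intron.intron_end - 140, first_intron.intron_end - 60, strand
            )
            alt_exons = exons[:-1] + [alt_e]
            donor = (chrom, exons[-2].end, alt_e.start)
            canonical_donor = (chrom, exons[-2].end, exons[-1].start)
        else:
            first_intron = tx.introns[0]
            alt_e = GenomicInterval(
                chrom, first_intron.intron_start + 60, first_intron.intron_start + 140, strand
            )
            alt_exons = [alt_e] + exons[1:]
            donor = (chrom, alt_e.end, exons[1].start)
            canonical_donor = (chrom, exons[0].end, exons[1].start)
        alt = Transcript(f"{gid}.tAFE", gid, strand, alt_exons)
        return (
            {"variant": donor, "others": (canonical_donor,)},
            alt,
            afe_event_id(gid, donor),
        )

    raise ConfigurationError(f"unhandled event type {etype}")


def simulate_annotation(
    cfg: SimulationConfig, rng: np.random.Generator
) -> Tuple[List[GeneModel], GroundTruth]:
    """Gene models hosting the planned events, plus the ground truth.

    Events flagged novel have their variant transcript omitted from the
    returned models (and hence from any GTF written from them) while staying
    in the ground truth; for intron retention "known" means a retention
    transcript whose exon spans the whole intron is emitted.
    """
    genes: List[GeneModel] = []
    cursor = 1_000
    for gi in range(cfg.n_genes):
        gene, cursor = _draw_gene(cfg, rng, gi, cursor)
        genes.append(gene)

    used_type: Dict[str, EventType] = {}
    used_introns: Dict[str, set] = {}
    events: List[TrueEvent] = []
    gene_cursor = 0
    for plan in cfg.event_plan:
        slot = None
        host = None
        for probe in range(cfg.n_genes):
            gene = genes[(gene_cursor + probe) % cfg.n_genes]
            prior = used_type.get(gene.gene_id)
            if prior is not None and not (
                prior is EventType.INTRON_RETENTION
                and plan.etype is EventType.INTRON_RETENTION
            ):
                continue
            slot = _host_capacity(
                gene, plan.etype, used_introns.get(gene.gene_id, set())
            )
            if slot is not None:
                host = gene
                gene_cursor = (gene_cursor + probe + 1) % cfg.n_genes
                break
        if host is None:
            raise ConfigurationError(
                f"event plan unsatisfiable: no gene can host {plan.etype.value}"
            )
        used_type[host.gene_id] = plan.etype
        if plan.etype is EventType.INTRON_RETENTION:
            used_introns.setdefault(host.gene_id, set()).add(slot["intron_idx"])

        novel = bool(rng.random() < cfg.novel_fraction)
        keys, alt_tx, event_id = _build_event_structure(host, plan.etype, slot, novel)
        if not novel and alt_tx is not None:
            host.transcripts.append(alt_tx)
            host.transcripts.sort(key=lambda t: (t.start, t.transcript_id))
        si = {}
        for cond in cfg.conditions:
            if cond == cfg.control or cond not in plan.phases:
                si[cond] = plan.baseline_si
            else:
                si[cond] = plan.baseline_si + plan.delta_si
        events.append(
            TrueEvent(
                event_id=event_id,
                etype=plan.etype,
                gene_id=host.gene_id,
                novel=novel,
                si_true=si,
                keys=keys,
            )
        )

    expression = {
        g.gene_id: float(
            rng.lognormal(cfg.expression_log_mean, cfg.expression_log_sigma)
        )
        for g in genes
    }
    fold: Dict[str, Dict[str, float]] = {
        g.gene_id: {c: 1.0 for c in cfg.conditions} for g in genes
    }
    gene_ids = [g.gene_id for g in genes]
    for cond in cfg.conditions:
        if cond == cfg.control:
            continue
        n_up = int(round(cfg.de_up_fraction * cfg.n_genes))
        n_down = int(round(cfg.de_down_fraction * cfg.n_genes))
        chosen = rng.choice(len(gene_ids), size=min(n_up + n_down, len(gene_ids)),
                            replace=False)
        for i, gi in enumerate(chosen):
            gid = gene_ids[int(gi)]
            if i < n_up:
                fold[gid][cond] = float(rng.uniform(*cfg.fold_up_range))
            else:
                fold[gid][cond] = float(rng.uniform(*cfg.fold_down_range))

    truth = GroundTruth(
        events=events,
        expression=expression,
        fold_change=fold,
        conditions=cfg.conditions,
        control=cfg.control,
    )
    return genes, truth


# ---------------------------------------------------------------------------
# Count synthesis


def _noise(cfg: SimulationConfig, rng: np.random.Generator, lam: float) -> int:
    if lam <= 0:
        return 0
    if cfg.noise == "nb":
        lam = rng.gamma(shape=1.0 / cfg.nb_dispersion, scale=lam * cfg.nb_dispersion)
    return int(rng.poisson(lam))


def intronic_read_positions(start: int, end: int, n: int, read_len: int) -> List[int]:
    """Deterministic tiling of n fully-intronic read start positions.

    Reads keep an 8 nt margin from both borders so they never bridge an
    exon–intron boundary; used by both the count tables (for depth/coverage)
    and the SAM writer, which keeps the two representations consistent.
    """
    span = end - start - read_len - 16
    if span < 0:
        span = 0
    return [start + 8 + (i * 37) % (span + 1) for i in range(n)]


def _intron_coverage_stats(
    start: int, end: int, positions: List[int], read_len: int
) -> Tuple[float, float]:
    if not positions:
        return 0.0, 0.0
    cov = np.zeros(end - start, dtype=np.int32)
    for p in positions:
        lo = max(p, start) - start
        hi = min(p + read_len, end) - start
        cov[lo:hi] += 1
    return float(cov.mean()), float((cov > 0).mean())


def simulate_counts(
    cfg: SimulationConfig,
    genes: List[GeneModel],
    truth: GroundTruth,
    rng: np.random.Generator,
) -> Tuple[JunctionCounts, EvidenceTable, Dict[str, Counter]]:
    """Junction counts, intron evidence and gene exonic-read counts.

    Per event and sample the informative total is ``depth``; variant support
    is drawn as noise(T·SI) and canonical as noise(T·(1−SI)).  IR boundary
    reads total noise(2·T·SI) split binomially between the two borders, with
    intronic reads noise(T·SI).  Junctions not owned by an event receive
    noise(background_depth).  Gene exonic counts are noise(expression·fold).
    """
    jc = JunctionCounts()
    ev = EvidenceTable()
    gene_counts: Dict[str, Counter] = {sm: Counter() for sm in cfg.conditions}

    event_owned: set = set()
    for tev in truth.events:
        event_owned.update(tuple(c) for c in tev.keys.values() if isinstance(c, tuple)
                           and not isinstance(c[0], tuple))
        if "others" in tev.keys:
            event_owned.update(tuple(c) for c in tev.keys["others"])

    gene_by_id = {g.gene_id: g for g in genes}

    for sm in cfg.conditions:
        # background junctions
        for g in genes:
            strand = g.strand
            for j in g.transcripts[0].introns:
                coords = j.coords
                if coords in event_owned:
                    continue
                n = _noise(cfg, rng, cfg.background_depth)
                if n > 0:
                    jc.add(coords, sm, n, strand)
        # events
        for tev in truth.events:
            T = cfg.depth
            si = tev.si_true[sm]
            strand = gene_by_id[tev.gene_id].strand
            if tev.etype is EventType.INTRON_RETENTION:
                coords = tev.keys["intron"]
                b = _noise(cfg, rng, T * (1 - si))
                if b > 0:
                    jc.add(coords, sm, b, strand)
                boundary_total = _noise(cfg, rng, 2 * T * si)
                left = int(rng.binomial(boundary_total, 0.5)) if boundary_total else 0
                right = boundary_total - left
                intronic = _noise(cfg, rng, T * si)
                if boundary_total or intronic:
                    rec = ev.record(coords, sm)
                    rec.left_boundary_count = left
                    rec.right_boundary_count = right
                    rec.intronic_read_count = intronic
                    pos = intronic_read_positions(
                        coords[1], coords[2], intronic, cfg.read_len
                    )
                    rec.mean_depth, rec.covered_fraction = _intron_coverage_stats(
                        coords[1], coords[2], pos, cfg.read_len
                    )
                ev.strand[coords] = strand
            elif tev.etype is EventType.EXON_SKIPPING:
                s = _noise(cfg, rng, T * si)
                u = _noise(cfg, rng, T * (1 - si))
                d = _noise(cfg, rng, T * (1 - si))
                for coords, n in ((tev.keys["skip"], s), (tev.keys["u"], u),
                                  (tev.keys["d"], d)):
                    if n > 0:
                        jc.add(coords, sm, n, strand)
            elif tev.etype in (EventType.ALT_5SS, EventType.ALT_3SS):
                v = _noise(cfg, rng, T * si)
                c = _noise(cfg, rng, T * (1 - si))
                if v > 0:
                    jc.add(tev.keys["variant"], sm, v, strand)
                if c > 0:
                    jc.add(tev.keys["canonical"], sm, c, strand)
            elif tev.etype is EventType.ALT_FIRST_EXON:
                v = _noise(cfg, rng, T * si)
                c = _noise(cfg, rng, T * (1 - si))
                if v > 0:
                    jc.add(tev.keys["variant"], sm, v, strand)
                for other in tev.keys["others"]:
                    if c > 0:
                        jc.add(other, sm, c, strand)
        # expression
        for g in genes:
            lam = truth.expression[g.gene_id] * truth.fold_change[g.gene_id][sm]
            n = _noise(cfg, rng, lam)
            gene_counts[sm][g.gene_id] = n
    return jc, ev, gene_counts


# ---------------------------------------------------------------------------
# SAM realisation


def simulate_alignments(
    cfg: SimulationConfig,
    genes: List[GeneModel],
    jc: JunctionCounts,
    ev: EvidenceTable,
    gene_counts: Dict[str, Counter],
    out_dir,
) -> Dict[str, Path]:
    """Realise the count tables as one valid SAM file per sample.

    Every junction count n becomes exactly n gap reads with ``anchor`` nt
    aligned on each side; boundary and intronic evidence become contiguous
    reads; gene counts become exon-internal reads.  Re-extracting the SAM
    reproduces the tables exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    contig_len = max(g.end for g in genes) + cfg.gene_gap
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": cfg.chrom, "LN": int(contig_len)}],
    }
    anchor = cfg.anchor
    rl = cfg.read_len
    gene_list = sorted(genes, key=lambda g: g.start)
    paths: Dict[str, Path] = {}
    samples = sorted(set(jc.samples) | set(ev.samples) | set(gene_counts))
    for sm in samples:
        path = out_dir / f"{sm}.sam"
        paths[sm] = path
        i = 0
        with pysam.AlignmentFile(str(path), "wh", header=header) as fh:

            def emit(pos: int, cigar: str) -> None:
                nonlocal i
                a = pysam.AlignedSegment(fh.header)
                a.query_name = f"{sm}.r{i:07d}"
                a.reference_id = 0
                a.reference_start = pos
                a.cigarstring = cigar
                a.mapping_quality = 60
                a.flag = 0
                fh.write(a)
                i += 1

            for coords in jc.keys():
                n = jc.get(coords, sm)
                if n <= 0:
                    continue
                _, s, e = coords
                cigar = f"{anchor}M{e - s}N{anchor}M"
                for _ in range(n):
                    emit(s - anchor, cigar)
            for coords in ev.keys():
                rec = ev.get(coords, sm)
                _, s, e = coords
                for _ in range(rec.left_boundary_count):
                    emit(s - rl // 2, f"{rl}M")
                for _ in range(rec.right_boundary_count):
                    emit(e - rl // 2, f"{rl}M")
                for p in intronic_read_positions(s, e, rec.intronic_read_count, rl):
                    emit(p, f"{rl}M")
            for g in gene_list:
                n = gene_counts.get(sm, Counter()).get(g.gene_id, 0)
                exons = g.transcripts[0].exons
                usable = [x for x in exons if x.length >= rl]
                if not usable:
                    continue  # exons shorter than the read length
                for k in range(n):
                    x = usable[k % len(usable)]
                    offset = (k * 13) % (x.length - rl + 1)
                    emit(x.start + offset, f"{rl}M")
    return paths


# ---------------------------------------------------------------------------
# Ground truth I/O


def write_ground_truth(truth: GroundTruth, events_path, genes_path) -> None:
    ev_rows = []
    for e in truth.events:
        row = {
            "event_id": e.event_id,
            "type": e.etype.value,
            "gene_id": e.gene_id,
            "novel": int(e.novel),
        }
        for cond in truth.conditions:
            row[f"si_{cond}"] = round(e.si_true[cond], 6)
        ev_rows.append(row)
    pd.DataFrame(ev_rows).to_csv(events_path, sep="\t", index=False)

    g_rows = []
    for gid in sorted(truth.expression):
        row = {"gene_id": gid, "expression": round(truth.expression[gid], 4)}
        for cond in truth.conditions:
            row[f"fold_{cond}"] = round(truth.fold_change[gid][cond], 6)
        g_rows.append(row)
    pd.DataFrame(g_rows).to_csv(genes_path, sep="\t", index=False)


def read_ground_truth(events_path, genes_path) -> GroundTruth:
    edf = pd.read_csv(events_path, sep="\t")
    conds = tuple(c[3:] for c in edf.columns if c.startswith("si_"))
    events = [
        TrueEvent(
            event_id=r.event_id,
            etype=EventType(r.type),
            gene_id=r.gene_id,
            novel=bool(r.novel),
            si_true={c: float(getattr(r, f"si_{c}")) for c in conds},
        )
        for r in edf.itertuples(index=False)
    ]
    gdf = pd.read_csv(genes_path, sep="\t")
    expression = {r.gene_id: float(r.expression) for r in gdf.itertuples(index=False)}
    fold = {
        r.gene_id: {c: float(getattr(r, f"fold_{c}")) for c in conds}
        for r in gdf.itertuples(index=False)
    }
    return GroundTruth(events, expression, fold, conditions=conds)


def simulate_dataset(
    cfg: SimulationConfig, seed: int, out_dir=None, alignments: bool = False
):
    """Convenience wrapper: annotation + truth + counts (+ optional SAMs).

    Returns ``(genes, truth, junction_counts, evidence, gene_counts, paths)``
    where ``paths`` maps sample -> SAM path when alignments are realised.
    """
    rng = np.random.default_rng(seed)
    genes, truth = simulate_annotation(cfg, rng)
    jc, ev, gcounts = simulate_counts(cfg, genes, truth, rng)
    paths: Dict[str, Path] = {}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_gtf(genes, out_dir / "annotation.gtf")
        jc.to_tsv(out_dir / "junctions.tsv")
        ev.to_tsv(out_dir / "intron_evidence.tsv")
        write_ground_truth(
            truth, out_dir / "truth_events.tsv", out_dir / "truth_genes.tsv"
        )
        gdf = pd.DataFrame(
            {sm: pd.Series(gcounts[sm]) for sm in sorted(gcounts)}
        ).fillna(0).astype(int)
        gdf.index.name = "gene_id"
        gdf.sort_index().to_csv(out_dir / "gene_counts.tsv", sep="\t")
        if alignments:
            paths = simulate_alignments(cfg, genes, jc, ev, gcounts, out_dir)
    elif alignments:
        raise ConfigurationError("alignments=True requires an out_dir")
    return genes, truth, jc, ev, gcounts, paths


def config_from_mapping(overrides: dict) -> SimulationConfig:
    """Build a config from a flat mapping (e.g. parsed YAML), type-checked."""
    fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(overrides) - fields
    if unknown:
        raise ConfigurationError(f"unknown simulation keys: {sorted(unknown)}")
    kwargs = dict(overrides)
    for key in ("exons_per_transcript", "exon_len", "intron_len", "conditions",
                "fold_up_range", "fold_down_range"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return SimulationConfig(**kwargs)
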