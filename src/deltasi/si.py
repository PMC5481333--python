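"""Splicing index (SI), ΔSI, and significance calling.

The SI of an event in one sample is ``a / (a + b)`` — the fraction of
informative reads supporting the variant isoform form.  How ``a`` and ``b``
are assembled from junction-proximal reads depends on the event class:

* IR:   a = round(mean(left boundary, right boundary)), b = spliced junction
* ES:   a = skip-junction count, b = round(mean(upstream, downstream))
* A5SS/A3SS: a = variant junction, b = canonical junction
* AFE:  a = this first-exon donor, b = sum of the gene's other donors

Each definition uses only reads adjacent to the decision point, never counts
the same spliced read twice (IR boundaries are averaged, not summed), and
reduces uniformly to a/(a+b).  ΔSI = SI(treated) − SI(control); events are
tested with a two-sided Fisher's exact test on the 2×2 count table and
corrected with Benjamini–Hochberg across all testable events of one
comparison.  The significance call is |ΔSI| ≥ dsi_min and q < fdr_max.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .events import CandidateEvent, EventType
from .junctions import EvidenceTable, JunctionCounts

DEFAULT_DSI_MIN = 0.15
DEFAULT_FDR_MAX = 0.01
DEFAULT_MIN_SUPPORT = 10


@dataclass
class SICounts:
    """Variant (a) and canonical (b) informative read support in one sample."""

    a: int
    b: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ValueError("support counts must be non-negative")


@dataclass
class SplicingCall:
    event_id: str
    etype: EventType
    gene_id: Optional[str]
    novel: bool
    control: SICounts
    treated: SICounts
    si_control: Optional[float]
    si_treated: Optional[float]
    delta_si: Optional[float]
    p_value: Optional[float]
    q_value: Optional[float]
    significant: bool

    @property
    def direction(self) -> Optional[str]:
        if self.delta_si is None or self.delta_si == 0:
            return None
        return "up" if self.delta_si > 0 else "down"


def round_half_away(x: float) -> int:
    """Round half away from zero (counts are non-negative here)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def event_support(
    event: CandidateEvent,
    junctions: JunctionCounts,
    evidence: EvidenceTable,
    sample_id: str,
) -> SICounts:
    """Per-type informative read support for one sample (docstring above)."""
    t = event.etype
    if t is EventType.INTRON_RETENTION:
        rec = evidence.get(event.intron, sample_id)
        a = round_half_away(
            (rec.left_boundary_count + rec.right_boundary_count) / 2.0
        )
        b = junctions.get(event.intron, sample_id)
    elif t is EventType.EXON_SKIPPING:
        a = junctions.get(event.skip, sample_id)
        u = junctions.get(event.upstream, sample_id)
        d = junctions.get(event.downstream, sample_id)
        b = round_half_away((u + d) / 2.0)
    elif t in (EventType.ALT_5SS, EventType.ALT_3SS):
        a = junctions.get(event.variant_j, sample_id)
        b = junctions.get(event.canonical_j, sample_id)
    elif t is EventType.ALT_FIRST_EXON:
        a = junctions.get(event.variant_j, sample_id)
        b = sum(junctions.get(c, sample_id) for c in event.other_donors)
    else:  # pragma: no cover - exhaustive enum
        raise ValueError(f"unknown event type {t}")
    return SICounts(a=a, b=b, sample_id=sample_id)


def compute_si(c: SICounts, min_support: int = DEFAULT_MIN_SUPPORT) -> Optional[float]:
    """SI = a/(a+b), undefined (None) below ``min_support`` informative reads."""
    total = c.a + c.b
    if total < min_support or total == 0:
        return None
    return c.a / total


def compute_delta_si(
    si_treated: Optional[float], si_control: Optional[float]
) -> Optional[float]:
    if si_treated is None or si_control is None:
        return None
    return si_treated - si_control


def test_event(control: SICounts, treated: SICounts) -> float:
    """Two-sided Fisher's exact p for [[a_t, b_t], [a_c, b_c]].

    Degenerate margins (an all-zero row or column) give p = 1.
    """
    table = [[treated.a, treated.b], [control.a, control.b]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(min(p, 1.0))


def adjust_fdr(p_values: Sequence[float]) -> List[float]:
    """Benjamini–Hochberg step-up q-values, order-preserving with input."""
    if len(p_values) == 0:
        return []
    q = multipletests(list(p_values), method="fdr_bh")[1]
    return [float(v) for v in q]


def call_events(
    events: Iterable[CandidateEvent],
    junctions: JunctionCounts,
    evidence: EvidenceTable,
    control_sample: str,
    treated_sample: str,
    dsi_min: float = DEFAULT_DSI_MIN,
    fdr_max: float = DEFAULT_FDR_MAX,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> List[SplicingCall]:
    """Score one treated-vs-control comparison for every candidate event.

    Events with undefined SI in either sample are retained in the output with
    blank statistics but excluded from the FDR pool.  The FDR is computed
    once across all five event types of the comparison.
    """
    if control_sample not in junctions.samples and control_sample not in evidence.samples:
        raise ValueError(f"control sample {control_sample!r} absent from counts")
    calls: List[SplicingCall] = []
    testable_idx: List[int] = []
    pvals: List[float] = []
    for event in events:
        sc = event_support(event, junctions, evidence, control_sample)
        st = event_support(event, junctions, evidence, treated_sample)
        si_c = compute_si(sc, min_support)
        si_t = compute_si(st, min_support)
        dsi = compute_delta_si(si_t, si_c)
        call = SplicingCall(
            event_id=event.event_id,
            etype=event.etype,
            gene_id=event.gene_id,
            novel=event.novel,
            control=sc,
            treated=st,
            si_control=si_c,
            si_treated=si_t,
            delta_si=dsi,
            p_value=None,
            q_value=None,
            significant=False,
        )
        if dsi is not None:
            testable_idx.append(len(calls))
            pvals.append(test_event(sc, st))
        calls.append(call)
    qvals = adjust_fdr(pvals)
    for i, p, q in zip(testable_idx, pvals, qvals):
        c = calls[i]
        c.p_value = p
        c.q_value = q
        c.significant = abs(c.delta_si) >= dsi_min and q < fdr_max
    return calls


def calls_to_frame(calls: Iterable[SplicingCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "event_id": c.event_id,
                "type": c.etype.value,
                "gene_id": c.gene_id if c.gene_id else "",
                "novel": int(c.novel),
                "a_control": c.control.a,
                "b_control": c.control.b,
                "a_treated": c.treated.a,
                "b_treated": c.treated.b,
                "si_control": "" if c.si_control is None else round(c.si_control, 6),
                "si_treated": "" if c.si_treated is None else round(c.si_treated, 6),
                "delta_si": "" if c.delta_si is None else round(c.delta_si, 6),
                "p_value": "" if c.p_value is None else f"{c.p_value:.6g}",
                "q_value": "" if c.q_value is None else f"{c.q_value:.6g}",
                "significant": int(c.significant),
                "direction": c.direction or "",
            }
        )
    cols = [
        "event_id", "type", "gene_id", "novel",
        "a_control", "b_control", "a_treated", "b_treated",
        "si_control", "si_treated", "delta_si",
        "p_value", "q_value", "significant", "direction",
    ]
    return pd.DataFrame(rows, columns=cols)
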