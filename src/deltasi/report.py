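"""Summary accounting over significance calls.

All percentages here recompute exactly from the underlying counts: per-type
composition of the significant events (pie-style shares at 2 dp and nearest
integer), up/down direction fractions per type, acute/chronic phase overlaps
as Venn counts with share-of-union, known/novel composition, and the squared
Pearson correlation used to express concordance between ΔSI estimates and
paired validation measurements.
"""

from __future__ import annotations

from collections import Counter
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .events import EventType
from .si import SplicingCall

TYPE_ORDER = [t.value for t in EventType]


def percentage(count: float, total: float, dp: int = 2) -> float:
    """count/total as a percentage rounded to dp decimals (0 if total == 0)."""
    if total == 0:
        return 0.0
    return round(100.0 * count / total, dp)


def _significant(calls: Iterable[SplicingCall]) -> List[SplicingCall]:
    return [c for c in calls if c.significant]


def summarize_event_types(calls: Iterable[SplicingCall]) -> pd.DataFrame:
    """Per-type counts with shares at 2 dp and nearest integer.

    Zero significant events yields all-zero shares with ``empty=True`` rows.
    """
    sig = _significant(calls)
    total = len(sig)
    counts = Counter(c.etype.value for c in sig)
    rows = []
    for t in TYPE_ORDER:
        n = counts.get(t, 0)
        rows.append(
            {
                "type": t,
                "count": n,
                "share_pct": percentage(n, total, 2),
                "share_int": int(round(percentage(n, total, 6))) if total else 0,
                "empty": total == 0,
            }
        )
    return pd.DataFrame(rows, columns=["type", "count", "share_pct", "share_int", "empty"])


def summarize_direction(
    calls: Iterable[SplicingCall], etype: Optional[EventType] = None
) -> Dict[str, float]:
    """Up/down counts and the up fraction (2 dp %) among significant calls."""
    sig = _significant(calls)
    if etype is not None:
        sig = [c for c in sig if c.etype is etype]
    up = sum(1 for c in sig if c.delta_si is not None and c.delta_si > 0)
    down = sum(1 for c in sig if c.delta_si is not None and c.delta_si < 0)
    total = up + down
    return {
        "up": up,
        "down": down,
        "total": total,
        "pct_up": percentage(up, total, 2),
        "pct_down": percentage(down, total, 2),
    }


def summarize_phase_overlap(
    calls_a: Iterable[SplicingCall],
    calls_b: Iterable[SplicingCall],
    label_a: str = "acute",
    label_b: str = "chronic",
) -> pd.DataFrame:
    """Per-type Venn of significant events across two comparisons.

    Events are matched by their deterministic event id, so "same event"
    means coordinate-identical.  Shares are reported against both the union
    (shared/|A ∪ B|) and each phase's own total.
    """
    ids_a: Dict[str, set] = {t: set() for t in TYPE_ORDER}
    ids_b: Dict[str, set] = {t: set() for t in TYPE_ORDER}
    for c in _significant(calls_a):
        ids_a[c.etype.value].add(c.event_id)
    for c in _significant(calls_b):
        ids_b[c.etype.value].add(c.event_id)
    rows = []
    for t in TYPE_ORDER + ["all"]:
        if t == "all":
            a = set().union(*ids_a.values())
            b = set().union(*ids_b.values())
        else:
            a, b = ids_a[t], ids_b[t]
        shared = len(a & b)
        union = len(a | b)
        rows.append(
            {
                "type": t,
                "shared": shared,
                f"{label_a}_only": len(a - b),
                f"{label_b}_only": len(b - a),
                "union": union,
                "shared_pct_of_union": percentage(shared, union, 2),
                f"shared_pct_of_{label_a}": percentage(shared, len(a), 2),
                f"shared_pct_of_{label_b}": percentage(shared, len(b), 2),
            }
        )
    return pd.DataFrame(rows)


def summarize_novelty(calls: Iterable[SplicingCall]) -> Dict[str, float]:
    """Known/novel counts and the novel fraction among significant calls."""
    sig = _significant(calls)
    novel = sum(1 for c in sig if c.novel)
    known = len(sig) - novel
    return {
        "known": known,
        "novel": novel,
        "total": len(sig),
        "pct_novel": percentage(novel, len(sig), 2),
    }


def concordance(x: Sequence[float], y: Sequence[float]) -> float:
    """R² as the squared Pearson correlation of paired measurements.

    Sign-blind by construction: perfectly anti-correlated pairs also give 1.
    Fewer than two pairs or zero variance in either vector is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("concordance requires paired vectors of equal length")
    if x.size < 2:
        raise ValueError("concordance undefined for fewer than 2 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("concordance undefined for zero-variance input")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def build_summary(
    calls_by_comparison: Mapping[str, Iterable[SplicingCall]],
) -> pd.DataFrame:
    """Long-format machine-readable summary over one or more comparisons."""
    rows: List[dict] = []

    def add(comparison, section, typ, metric, value):
        rows.append(
            {
                "comparison": comparison,
                "section": section,
                "type": typ,
                "metric": metric,
                "value": value,
            }
        )

    lists = {k: list(v) for k, v in calls_by_comparison.items()}
    for comp, calls in lists.items():
        sig = _significant(calls)
        add(comp, "totals", "all", "significant_events", len(sig))
        add(comp, "totals", "all", "testable_events",
            sum(1 for c in calls if c.p_value is not None))
        types = summarize_event_types(calls)
        for rec in types.itertuples(index=False):
            add(comp, "composition", rec.type, "count", rec.count)
            add(comp, "composition", rec.type, "share_pct", rec.share_pct)
        for etype in EventType:
            d = summarize_direction(calls, etype)
            add(comp, "direction", etype.value, "up", d["up"])
            add(comp, "direction", etype.value, "down", d["down"])
            add(comp, "direction", etype.value, "pct_up", d["pct_up"])
        nov = summarize_novelty(calls)
        add(comp, "novelty", "all", "known", nov["known"])
        add(comp, "novelty", "all", "novel", nov["novel"])
        add(comp, "novelty", "all", "pct_novel", nov["pct_novel"])

    comps = list(lists)
    if len(comps) >= 2:
        a, b = comps[0], comps[1]
        overlap = summarize_phase_overlap(lists[a], lists[b], a, b)
        for rec in overlap.itertuples(index=False):
            add(f"{a}|{b}", "phase_overlap", rec.type, "shared", rec.shared)
            add(f"{a}|{b}", "phase_overlap", rec.type, f"{a}_only",
                getattr(rec, f"{a}_only"))
            add(f"{a}|{b}", "phase_overlap", rec.type, f"{b}_only",
                getattr(rec, f"{b}_only"))
            add(f"{a}|{b}", "phase_overlap", rec.type, "shared_pct_of_union",
                rec.shared_pct_of_union)
    return pd.DataFrame(rows, columns=["comparison", "section", "type", "metric", "value"])


def spliced_gene_set(calls: Iterable[SplicingCall]) -> set:
    """Genes carrying >= 1 significant event (events collapsed to genes)."""
    return {
        c.gene_id for c in _significant(calls) if c.gene_id
    }
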