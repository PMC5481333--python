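"""Gene-level expression counting, fold-change calls and set overlaps.

With a single library per condition, differential expression here is the
fold-change gate alone: genes whose CPM ratio reaches ``fc_min`` (default
1.5, boundary inclusive) are called up, the reciprocal down, the rest
unchanged.  Reads are assigned to a gene when an aligned block overlaps the
gene's exonic union; reads touching exons of more than one gene are dropped
as ambiguous and intronic-only reads do not count toward expression.
"""

from __future__ import annotations

from collections import Counter
from itertools import combinations
from typing import Dict, Iterable, Mapping, Set

import pandas as pd

from .annotation import AnnotationIndex
from .junctions import AlignedRead

DEFAULT_FC_MIN = 1.5
DEFAULT_PSEUDOCOUNT = 0.5


def count_gene_reads(
    reads: Iterable[AlignedRead], index: AnnotationIndex
) -> Dict[str, Counter]:
    """Raw exonic read counts per (sample, gene); ambiguous reads dropped."""
    counts: Dict[str, Counter] = {}
    for read in reads:
        blocks, _ = read.blocks_and_gaps()
        genes: set = set()
        for bs, be in blocks:
            genes |= index.genes_with_exon_overlap(read.chrom, bs, be)
        if len(genes) == 1:
            counts.setdefault(read.sample_id, Counter())[next(iter(genes))] += 1
        else:
            counts.setdefault(read.sample_id, Counter())
    return counts


def normalize_cpm(
    raw: Mapping[str, Mapping[str, int]],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Counts per million assigned reads, pseudocount-stabilised.

    value = (count + pseudocount) / total_assigned * 1e6, where the total is
    the sum of raw assigned counts in that sample (pseudocount excluded).
    """
    genes = sorted({g for ctr in raw.values() for g in ctr})
    samples = sorted(raw)
    data = {}
    for sm in samples:
        total = sum(raw[sm].values())
        if total <= 0:
            raise ValueError(f"sample {sm!r} has zero assigned reads")
        data[sm] = [
            (raw[sm].get(g, 0) + pseudocount) / total * 1e6 for g in genes
        ]
    return pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))


def fold_changes(
    cpm: pd.DataFrame, treated: str, control: str
) -> pd.Series:
    """Per-gene fold change of normalised values, treated over control."""
    return cpm[treated] / cpm[control]


def call_differential(
    fold: pd.Series, fc_min: float = DEFAULT_FC_MIN
) -> pd.Series:
    """up / down / unchanged per gene; the >= fc_min gate is inclusive."""
    if fc_min <= 1:
        raise ValueError("fc_min must exceed 1")

    def one(f: float) -> str:
        if f >= fc_min:
            return "up"
        if f <= 1.0 / fc_min:
            return "down"
        return "unchanged"

    return fold.map(one)


def expression_table(
    raw: Mapping[str, Mapping[str, int]],
    treated: str,
    control: str,
    fc_min: float = DEFAULT_FC_MIN,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Raw counts, CPM, fold change and call for one comparison."""
    cpm = normalize_cpm(raw, pseudocount)
    fold = fold_changes(cpm, treated, control)
    call = call_differential(fold, fc_min)
    out = pd.DataFrame(
        {
            f"raw_{control}": [raw[control].get(g, 0) for g in cpm.index],
            f"raw_{treated}": [raw[treated].get(g, 0) for g in cpm.index],
            f"cpm_{control}": cpm[control].round(4),
            f"cpm_{treated}": cpm[treated].round(4),
            "fold_change": fold.round(6),
            "call": call,
        },
        index=cpm.index,
    )
    return out


# ---------------------------------------------------------------------------
# Set overlaps


class OverlapPartition:
    """Exact Venn cells for 2–4 named sets plus optional fractions.

    ``cells`` maps a frozenset of set names to the number of elements
    belonging to exactly those sets; cells partition the union.
    """

    def __init__(self, sets: Mapping[str, Iterable]):
        if not 2 <= len(sets) <= 4:
            raise ValueError("overlap_partition requires 2-4 sets")
        self.sets: Dict[str, Set] = {name: set(vals) for name, vals in sets.items()}
        names = sorted(self.sets)
        universe = set().union(*self.sets.values())
        self.cells: Dict[frozenset, int] = {}
        for r in range(1, len(names) + 1):
            for combo in combinations(names, r):
                inside = set(universe)
                for n in combo:
                    inside &= self.sets[n]
                for n in names:
                    if n not in combo:
                        inside -= self.sets[n]
                self.cells[frozenset(combo)] = len(inside)
        self.union_size = len(universe)

    def cell(self, *names: str) -> int:
        return self.cells[frozenset(names)]

    def intersection(self, *names: str) -> int:
        inside = set.intersection(*(self.sets[n] for n in names))
        return len(inside)

    def fractions(self, denominator: int = None) -> Dict[frozenset, float]:
        denom = self.union_size if denominator is None else denominator
        if denom <= 0:
            return {k: 0.0 for k in self.cells}
        return {k: v / denom for k, v in self.cells.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        fracs = self.fractions()
        for key in sorted(self.cells, key=lambda k: (len(k), sorted(k))):
            rows.append(
                {
                    "cell": "&".join(sorted(key)),
                    "count": self.cells[key],
                    "fraction_of_union": round(fracs[key], 6),
                }
            )
        return pd.DataFrame(rows, columns=["cell", "count", "fraction_of_union"])


def overlap_partition(sets: Mapping[str, Iterable]) -> OverlapPartition:
    """Venn cells over 2–4 named sets (duplicates within a set deduplicated)."""
    return OverlapPartition(sets)


def expression_splicing_overlap(
    de_up: Iterable, de_down: Iterable, spliced_genes: Iterable
) -> pd.DataFrame:
    """Overlap of DE genes with genes carrying >= 1 significant splicing event.

    Fractions use the union of all three sets as denominator, the accounting
    behind printed ratios like "39/2518": the denominator is every gene that
    showed an expression and/or splicing change.
    """
    up, down, spl = set(de_up), set(de_down), set(spliced_genes)
    union = up | down | spl
    denom = len(union)
    rows = [
        ("up_and_spliced", len(up & spl)),
        ("down_and_spliced", len(down & spl)),
        ("up_only", len(up - spl)),
        ("down_only", len(down - spl)),
        ("spliced_only", len(spl - up - down)),
        ("union", denom),
    ]
    return pd.DataFrame(
        [
            {
                "cell": name,
                "count": n,
                "fraction_of_union": round(n / denom, 6) if denom else 0.0,
            }
            for name, n in rows
        ],
        columns=["cell", "count", "fraction_of_union"],
    )
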