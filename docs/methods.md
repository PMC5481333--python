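# Methods

## Model and procedure

`deltasi` treats differential alternative splicing as a shift in the
proportion of an alternative isoform form at a single decision point.  For
every candidate event and library, informative reads are split into variant
support `a` and canonical support `b`, and the splicing index is

    SI = a / (a + b)  ∈ [0, 1],

the analogue of PSI ("percent spliced in").  The effect statistic for a
treated-vs-control comparison is ΔSI = SI_treated − SI_control ∈ [−1, 1];
ΔSI > 0 always means the variant form (retention, skipping, alternative
donor/acceptor/first exon) increases under treatment.  Each testable event
is assigned a two-sided Fisher's exact p-value on the table
[[a_t, b_t], [a_c, b_c]] and a Benjamini–Hochberg q-value computed once per
comparison across all testable events of all five classes pooled.  An event
is called significant when |ΔSI| ≥ `dsi_min` (default 0.15) **and**
q < `fdr_max` (default 0.01); both gates are applied jointly after the FDR
is computed over the full testable pool.

The single-replicate design (n = 1 library per condition) shapes the
statistics: Fisher's exact test models only read-sampling noise, not
biological replication, so q-values state evidence against "no change in
this pair of libraries", not population-level inference.  That is the
reason for the effect-size gate alongside the FDR gate, and for the absence
of any dispersion-modelled expression test (expression calls are a plain
≥1.5-fold CPM-ratio gate).

## Read classification

Relative to annotated splice sites, each mapped read falls in exactly one
group; gap evidence dominates:

1. **Exon–exon** — the read has an N gap with ≥ `min_overhang` (default
   6 nt) aligned on each side.  Each anchored gap increments the junction
   keyed by its intron interval (chrom, gap start, gap end).
2. **Exon–intron** — a contiguous read spanning an annotated exon–intron
   border with ≥ `min_overhang` nt on each side of the border.
3. **Intronic** — a contiguous read fully inside an annotated intron.
   These reads never enter significance calling; they only provide
   intron-retention depth and covered fraction.

Everything else is unclassified.  A read is "fully intronic" for intron J
only if it overlaps no annotated exon nested inside J: reads over a
cassette exon are exonic even though the skipping isoform's intron
contains them, whereas an annotated retention exon spanning all of J does
not disqualify J.  Deletions (D) extend aligned blocks; only N creates
junction gaps.  Multi-mapped and low-quality alignments are excluded
(mapping quality ≥ 1 by default).  These read filters are declared,
configurable choices of this implementation.

## Per-type SI support

Each class uses only junction-proximal reads and reduces uniformly to
a/(a+b):

| class | variant support a              | canonical support b            |
|-------|--------------------------------|--------------------------------|
| IR    | round(mean(left, right border))| spliced junction count         |
| ES    | skip junction count            | round(mean(upstream, downstream)) |
| A5SS/A3SS | variant junction count     | canonical junction count       |
| AFE   | this first-exon donor count    | sum of the gene's other donors |

Averaging the two IR boundaries (rather than summing) avoids giving the
retention form twice the weight per read that the spliced form gets;
averaging the ES flanks avoids double-counting the inclusion isoform.
Fractional means are rounded half away from zero so the exact test sees
integers.  SI is undefined below `min_support` (default 10) informative
reads in a sample; events with an undefined SI on either side are excluded
from the FDR pool but retained in the output.

## Event detection and novelty

Candidates are enumerated from the union of observed and annotated
junctions, so unannotated variants are detectable:

* **IR** — one event per intron (annotated, or the interval of an observed
  novel junction) with any spliced or boundary evidence.  An IR event is
  *known* only if some annotated transcript retains the intron inside an
  exon; retention of an annotated intron without such an isoform is novel.
* **ES** — junction triples (u, d, s) with s sharing its start with u and
  its end with d; the middle exon [u_end, d_start) comes from junction
  geometry (novel cassette exons detectable) and is capped at 10 kb to
  guard against chimera-like triples.  When several (u, d) pairs frame one
  skip junction, the annotated consecutive pair is preferred, else the
  most-supported pair.
* **A5SS/A3SS** — junction pairs sharing the acceptor (5′) or donor (3′),
  strand-aware.  The canonical junction is the annotated one; if zero or
  several are annotated, the junction with the higher control-library
  count wins, ties going to the longer intron.  Strandless junction groups
  are skipped; unknown strands are first resolved from the unique
  overlapping gene.
* **AFE** — per gene with ≥ 2 first-exon donor junctions, one event per
  donor against the pooled others.  A novel first-exon donor is an
  observed unannotated junction splicing into the acceptor used by the
  gene's annotated first-exon donors, with its donor side outside all
  annotated exons.  Requiring *that* acceptor (not any annotated acceptor)
  keeps novel internal donors classified as A5SS/A3SS variants.  Two
  disambiguation rules follow from the overlap of the AFE and A5SS
  definitions: first-exon donor junctions of multi-first-exon genes are
  excluded from A5SS grouping, and AFE novelty is keyed on the event's own
  variant donor (one novel first exon does not relabel the gene's
  annotated first-exon events).

Event identifiers are deterministic functions of class and coordinates, so
"the same event" across comparisons or across simulator/detector is
coordinate-identical.  Events whose evidence spans zero or several genes
are flagged ambiguous and excluded from gene-level summaries.  Mutually
exclusive exons, alternative last exons and complex events are outside the
five-class taxonomy and not modelled.  One event per candidate is counted
in all summaries (an ES triple is one event, not three junctions).

## Expression calls and overlaps

Reads are assigned to a gene when an aligned block overlaps its exonic
union; reads touching exons of two genes are dropped as ambiguous.  Counts
are normalised to CPM with a 0.5 pseudocount for fold-change stability at
zero, and genes are called up/down at a boundary-inclusive ≥1.5-fold gate.
Venn cells for 2–4 named gene sets are computed exactly; the
expression-vs-splicing overlap reports fractions over the union of the DE
and spliced gene sets (every gene showing an expression and/or splicing
change), which is the accounting behind ratios like "39/2518".

## Synthetic data

The generator emulates the target data regime: three conditions (a control
plus two treatment phases), one library each, multi-isoform genes, and a
planned set of true events.  Defaults: 200 genes of 4–8 exons
(100–300 nt) and introns of 200–1000 nt on alternating strands; 60 events
split IR 40% / ES 20% / A5SS 15% / A3SS 15% / AFE 10% with
ΔSI_true ∈ {0, ±0.2, ±0.4} cycling over acute-only / chronic-only / both
phases; baseline SI 0.3 (0.5 for negative effects; 0.4 for negative alt-SS
effects so the canonical junction stays the control-library majority);
200 informative reads per event and sample; 50 reads on non-event
junctions; 75% of events novel (their variant structure omitted from the
emitted GTF); gene expression log-normal (median ≈150 exonic reads) with
10% of genes up- and 5% down-regulated per phase at 1.6–4-fold; Poisson
counts (negative binomial with dispersion 0.05 available); 80 nt
single-end reads with 40 nt anchors.  Counts are drawn as
variant ~ Pois(T·SI), canonical ~ Pois(T·(1−SI)); IR boundary reads total
Pois(2·T·SI) split binomially between the borders, with intronic reads
Pois(T·SI) tiled deterministically so the coverage in the count tables and
in the realised SAM agree exactly.

What the simulator does **not** emulate: nucleotide sequence and alignment
error (reads are placed, not aligned), paired-end structure, fragment-length
variation, positional coverage bias, expression-coupled junction depth,
overlapping genes, and biological replication.  Passing tests therefore
demonstrate the correctness of the counting, detection and calling
machinery under the stated noise model — not robustness to alignment
artefacts in real data.

## Numerical and design choices

* Internal coordinates are 0-based half-open everywhere; GTF is converted
  exactly once at the I/O boundary and written back losslessly.
* Junction identity is the intron interval; STAR `SJ.out.tab` rows
  (1-based inclusive) are converted on read, using unique-mapping counts.
* Fisher p-values come from scipy; BH q-values from statsmodels.  Both are
  cross-checked in the test suite against independent brute-force oracles
  (exhaustive hypergeometric enumeration; the naive quadratic BH
  definition).  The statistical test and FDR procedure are this package's
  explicit choices for an otherwise unspecified "p-value + FDR" scheme.
* Degenerate 2×2 margins give p = 1.  ΔSI = 0 has no direction.
* All stages are deterministic: one seeded generator drives the simulator,
  tables are sorted before writing, and a rerun with the same
  configuration and seed is byte-identical.

## Problem sizes used in the checks

The packaged verification runs at desk scale, chosen to exercise every
code path with comfortable statistical margins: round-trip extraction on
the 200-gene default fixture (3 SAM libraries, ~300 k reads); calibration
on 2000 null IR events at 100 informative reads (observed q < 0.01
fraction ~0); recovery on 240 events with |ΔSI_true| ∈ {0.3, 0.4} at 150
informative reads (sensitivity ≈ 99%, mean |ΔSI error| ≈ 0.04).  The
published-scale event totals from ~180 M-read libraries are not
reproducible at this scale; the summary arithmetic over the printed
tallies is reproduced exactly instead.

## Known limitations

* No replicate-aware model: with n > 1 libraries per condition the Fisher
  test would overstate confidence; a beta-binomial layer would be needed.
* AFE detection requires a spliced first exon; promoter switches expressed
  only through coverage (no junction change) are invisible.
* The canonical-junction choice for alt-SS events falls back to read
  counts when annotation is ambiguous; a deeply expressed novel variant
  can in principle displace the annotated canonical orientation.
* Events are matched across comparisons by exact coordinates; fuzzy
  matching of slightly shifted novel junctions is not attempted.
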