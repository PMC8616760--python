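# Methods

## Coordinate conventions

All intervals are 0-based, half-open, on the forward strand.  GFF3 input
(1-based, fully closed) is converted at the reader boundary; BED passes
through unchanged; writers invert the conversion, and GFF3→internal→GFF3
and BED→internal→BED round trips are exact for coordinates and strand.
Chromosome names are compared as exact strings — no implicit "chr"
aliasing — because silent aliasing corrupts intersections.

The transcription start site of a gene is `body.start` on the + strand and
`body.end − 1` on the − strand; it depends only on the gene body and
strand, never on the exon structure.

## Peak-to-TSS distance and feature classes

A peak is reduced to a point anchor: its summit when one was recorded,
otherwise the interval midpoint (floor for even lengths); a `nearest_edge`
anchor is also available and returns distance 0 for a peak overlapping the
TSS.  The signed distance is (anchor − TSS), negated for − strand genes, so
negative always means upstream in the gene's own orientation.

Feature classification uses the priority promoter > exon > intron >
intergenic.  "Promoter" means |TSS distance| ≤ a half-width (default
5000 bp) on *either* side of the TSS; an upstream-only mode
(−half-width ≤ d ≤ 0) is selectable because promoter-walking qPCR designs
conventionally tile only the upstream side.  The boundary is inclusive
("within" read as ≤).  Exon/intron membership is judged at the point
anchor.  Among several qualifying genes the one with the smallest |TSS
distance| is assigned, ties broken lexicographically by gene id — a
deterministic artifact decision, not a biological claim.

## DEG selection

up = {log2FC > t, padj < α}, down = {log2FC < −t, padj < α} with strict
inequalities on both thresholds (defaults t = 0.585 ≈ log2 1.5, α = 0.05);
boundary genes are excluded.  Selection is annotation-independent: genes in
the DE table with no gene model are kept here and dropped, with a recorded
count, only at integration.

## Target integration

Candidacy requires ≥ 1 peak whose anchor lies within the window (default
5000 bp, symmetric, inclusive) of the gene's TSS *and* membership in the
up or down DEG set.  For candidacy every gene within the window of a peak
counts — one peak may support several genes — unlike the single-gene
assignment used for feature summaries, so a bound gene is never missed
because a neighbour is nearer.  The regulation label combines the DE sign
with the perturbation design: knockdown maps − → transactivated and
+ → repressed; overexpression mirrors it.  Output is sorted by
(regulation, min |TSS distance|, gene id); the ranking key is an artifact
convenience.  Genes with proximal peaks but no DE record are reported in a
"bound, not assayed" sidecar.

## Validation-assay arithmetic

*Motif scanning.*  Exact IUPAC matching; an `N` in the *sequence* is an
unknown base and never matches, even against motif `N`.  Minus-strand hits
(matches of the reverse-complemented motif) are reported at forward-strand
coordinates of the match start so downstream joins live in one coordinate
frame.  Overlapping hits are all reported.

*Tiling windows.*  Left-aligned consecutive windows partitioning
[start, end) in TSS-relative coordinates, the last window truncated; the
count is ⌈span/width⌉.

*Percent input.*  100 × 2^((Ct_input − log2(1/f)) − Ct_IP) with input
fraction f: the input Ct is first adjusted to its 100% equivalent, then the
IP is expressed relative to it.  The two common textbook variants differ
only in where the dilution factor enters; this form is fixed, documented,
and pinned by its definitional fixed point (IP at the adjusted input Ct
gives exactly 100%).  Values above 100% are returned but flagged.  Fold
enrichment over the IgG control is the ratio of percent inputs and equals
2^(Ct_IgG − Ct_ab) algebraically.

## Median-effect and combination index

The median-effect equation fa/(1−fa) = (D/Dm)^m is fitted by ordinary least
squares on (log10 D, log10(fa/(1−fa))); m is the slope,
Dm = 10^(−intercept/m), r the correlation of the linearised points.  fa
values of exactly 0 or 1 are clamped to [1e−4, 1−1e−4] with a warning
(strict mode rejects) because the logit is undefined at the boundary.
Curves must be monotone increasing in effect; a non-positive fitted slope
is an error rather than a silent nonsense Dm.  CI is computed at the
combination's *observed* fa (constant-ratio Chou–Talalay convention);
isobologram intercepts at a chosen fa support the fixed-effect view.  The
additive/synergistic/antagonistic call uses a tolerance band ±ε (default
0.05) around CI = 1, since an exact trichotomy is vacuous on noisy data;
ε = 0 restores the strict version.

## Fisher's exact test

Two-sided p by full hypergeometric enumeration over the support with fixed
margins, point-probability convention: the sum of the probabilities of all
tables no more probable than the observed one, with a relative tie
tolerance of 1e−7 to guard against floating-point near-ties.  This is the
convention under which a 9/11 vs 4/13 incidence table yields p = 0.019; the
"doubling" convention (twice the smaller tail, capped at 1) is available as
an option.  Kaplan–Meier/Cox-style survival statistics are deliberately out
of scope: they operate on patient-level data this package never sees and
are served by standard survival libraries.

## Synthetic data: what it emulates and what it does not

The generator produces a single-chromosome genome (default 10 Mb, i.i.d.
uniform bases) with `n_genes` non-overlapping genes placed by bounded
rejection sampling, strands from fair coin flips, and 0–3 non-overlapping
exons per gene.  Each designated target gene receives exactly one peak with
summit uniform within ±2000 bp of its TSS (well inside the 5000-bp
integration window); background peaks are placed uniformly at least 10 kb
from every TSS, so in the zero-noise regime sensitivity = specificity = 1.0
is the *designed* outcome and any deviation is a pipeline defect.  The DE
table gives targets log2FC = s·(1.0 + N(0, 0.1)) with the sign s implied by
the regulation label and the design, and significant padj drawn uniformly
from (1e−6, 0.01); null genes get N(0, 0.2) fold changes and padj in
(0.05, 1.0).  padj values are assigned directly from these ranges rather
than simulated through a count model — DE model fitting is out of scope and
the pipeline consumes only (log2FC, padj).  A separate fixture mode plants
exact up/down counts (default 1004 and 355) for funnel-count checks.
Dose–response curves come from the median-effect equation with optional
logit-scale Gaussian noise, and a Loewe-additive combination generator
places points exactly on the additivity isobole.

What this does *not* emulate: fragment-level ChIP coverage and peak-caller
artifacts, correlated expression noise, multiple peaks per target,
mappability structure, or realistic promoter sequence composition.  Passing
the recovery tests therefore demonstrates the correctness of the
integration logic, not the error rates to expect on real ChIP-seq/RNA-seq
data, where both filters trade off sensitivity against specificity.

One global seed fans out to fixed, CRC-labelled substreams
(`numpy` `SeedSequence(seed, spawn_key=(crc32(label),))`), so regenerating
one component never perturbs another and identical seeds give byte-identical
files; the seed is recorded in every output header and in the truth JSON.

## Problem sizes

The default study size — 100 genes on 10 Mb, 8 planted targets, 200
background peaks — exercises every code path while keeping a full simulate →
integrate cycle around a second; the brute-force cross-checks use up to
50 genes × 200 peaks and all 2×2 tables with total ≤ 20, sizes at which
exhaustive oracles are exact and fast.  Larger genomes or peak sets only
change runtime, not logic: every algorithm is linear or near-linear in
genes × peaks per chromosome.

## Known limitations

Per-gene (not per-transcript) TSS; no UTR/TTS feature classes; no BAM/FASTQ
handling or liftover; CI analysis assumes both single agents follow the
median-effect model (r of the linearised fit is reported so poor fits are
visible); the Fisher enumeration targets small tables — for totals in the
thousands a normal approximation or scipy's implementation is preferable.
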