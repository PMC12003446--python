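# Methods

## Scope and data model

circkit analyses back-splice junction (BSJ) call tables in the CIRI2 output
dialect together with an Ensembl-dialect GTF, a genome FASTA, a BED6 repeat
track, a sample sheet (sample → case/control group, mappable-read total)
and, optionally, a cassette-exon table with PSI values and an exon-chain
table. All coordinates are handled 1-based inclusive internally (the
convention of CIRI2 and GTF); BED is converted on read and the conversion
round-trips exactly. Chromosome names are matched as exact strings.
Duplicate call rows for one (chrom, start, end, strand) within a sample are
merged by summing reads, with a logged warning. Intergenic calls are parsed
and retained but flagged, and excluded from locus-level analyses.

## Confidence tiers

The three read-support filters are independent predicates per circRNA over
the samples of the analysed matrix:

| tier | rule | default parameters |
|---|---|---|
| 1 | max count over samples ≥ 2 | — |
| 2 | present in ≥ 2 samples AND total ≥ 5 | presence = count ≥ 1 |
| 3 | present in ≥ (n − 1) samples | presence = count ≥ 1 |

Two readings of the tier-2 rule circulate (presence in ≥ 2 samples with a
total of ≥ 5 reads, versus ≥ 5 reads in each of ≥ 2 samples); the first is
the default and the second is available as `tier2_rule="per_sample"`.
Tier 3 asks for presence *regardless of read number*, so the tiers are
deliberately not nested: a tier-3 circRNA can fail tier 1. For a
single-sample matrix the tier-3 presence requirement is floored at one
sample, so an all-zero row is never "present in all samples". Tiers are
computed over all columns of the supplied matrix; callers compare groups by
subsetting first if desired.

## Quantification and differential abundance

Expression is reads per million mappable reads, `RPM = count × 10⁶ /
mappable_reads`, applied identically to junction and non-junction counts.
The differential test is a two-tailed two-sample t-test on untransformed
RPM values. Welch (unequal variances) is the default — the de facto default
of common statistical environments — with pooled-variance Student and a
log2(RPM + ε) transform available by flag. The fold change is
`log2((mean_case + ε)/(mean_control + ε))` with ε = 0.01 RPM, a pseudocount
small enough not to distort typical RPMs while keeping zero-control
circRNAs finite. Direction calls use log2FC ≥ 1 (≤ −1) and p < 0.05, both
configurable. No multiple-testing correction is applied by default (raw
p-values are combined with the fold-change threshold); Benjamini–Hochberg
is available by flag. Degenerate rows with zero variance in both groups get
p = 1 (and log2FC = 0) when the group means are equal, p = 0 otherwise.
Direction splits are compared with Pearson's chi-squared test without
continuity correction; a single split is tested against 50:50.

## Structural classification

Each BSJ end receives a context against the host gene's transcripts with
the precedence exon_boundary (exact coordinate match, ± a configurable slop
that defaults to 0 because CIRI2 coordinates are splice-site resolved) >
inside_exon > inside_intron > outside_gene. Categories follow from the
context pair: both ends exonic → exonic; both inside one intron →
intronic; both inside different introns, or one exonic and one intronic →
exonic+intronic; one or both ends outside the gene → the intergenic-mixed
categories or intergenic. Classification runs against the gene named in
the record; records without a gene are resolved to the maximally
overlapping gene and flagged ambiguous. Strand mismatches between record
and gene are flagged but do not change the call (both strands are used in
circRNA formation). Length is the genomic span by default — spliced length
is only known when exon chains are supplied — and is binned at
[200, 1000, 5000] nt with inclusive lower edges.

Genes are split into single-circRNA genes (SCG, one distinct BSJ) and
multi-circRNA genes (MCG, ≥ 2), with "top" MCGs hosting more than 10.
Isoform groups are formed three ways: same-BSJ groups when exon-chain
evidence shows ≥ 2 internal compositions for one BSJ, and shared-donor /
shared-acceptor groups over distinct BSJs of one gene sharing exactly one
end (the donor end is the 3′ end in transcript orientation).

## Locus features

**Host transcript.** The longest transcript containing both BSJ ends, ties
broken by lexicographic transcript id; failing that, the longest
overlapping transcript.

**Flanking introns.** The nearest intron entirely 5′ (upstream) and 3′
(downstream) of the circRNA in transcript orientation; first/last-exon
circRNAs get a missing value on the absent side. Remaining introns of the
host transcript serve as "other" controls, optionally subsampled with a
seeded generator. Group comparisons use the pooled-variance Student t-test
(two-tailed); zero-variance degenerate groups get p = 1 on equal means.

**RCM detection.** Every annotated repeat inside the upstream flanking
intron is aligned locally (Smith–Waterman scoring: match +1, mismatch −1,
gap −2) against the reverse complement of every repeat inside the
downstream intron, so only inverted — base-pairing-capable — pairs can
score. A pair is reported when the best local alignment spans ≥ 20 columns
at ≥ 80% identity; both thresholds and the scoring triplet are
configurable and were chosen as a conservative proxy for a
MegaBLAST-style search. Duplex free energies are out of scope; the result
type leaves room for an externally computed ΔG column.

**Splice-site strength.** Scores are computed over the canonical
maximum-entropy-model windows — donor 9 nt (3 exonic + 6 intronic),
acceptor 23 nt (20 intronic + 3 exonic), in transcript orientation. The
scoring model is pluggable behind a two-method interface (`score_donor`,
`score_acceptor`); the built-in default is a first-order-free log2-odds
position weight matrix estimated from all annotated splice sites of the
supplied GTF with additive smoothing (pseudocount 1) against genome-wide
base frequencies. A matrix whose position probabilities equal the
background scores exactly 0 for any sequence, which anchors the scale.
Published maximum-entropy score tables can be wrapped in the same
interface when available. For a BSJ the windows of the back-splice's own
would-be splice sites are scored (the flanks immediately outside the
circle); windows running off a contig or containing N score missing.

**BSJ end classes.** An end is `annotated` when it exactly matches an
annotated exon boundary on its own side (starts against exon starts, ends
against exon ends), `ie` inside an exon (with a last-exon flag), `ii`
inside an intron (with the transcript-orientation intron ordinal), or
`intergenic`. Dinucleotides are read immediately outside the BSJ — the
ends of the would-be intron of the circularizing event — and the canonical
flag requires GT after the donor and AG before the acceptor on the
transcript strand (DNA alphabet; GU/AG in RNA).

## Motif profiling

MBNL1 motifs default to all 4-mers matching YGCY plus the literal 5-mers
UGCUU and GCUGC (GCUGC does not itself match YGCY, so it is listed
explicitly); the CUGBP1 UG-rich signal defaults to overlapping UGUG
occurrences, with a run-based alternative (maximal (UG)n, n ≥ 3). Counting
is overlapping — the common CLIP-motif convention and the more sensitive
choice — with U ≡ T on both sides and N never matching. Three regions are
profiled per circRNA in transcript orientation: the exon body (the BSJ
span) and 250-nt windows hugging the circRNA in the upstream and
downstream flanking introns, truncated (and flagged) when an intron is
shorter than the window. Outputs are sequence-motif counts only; no claim
of in vivo binding is made.

Single-exon circRNAs (BSJ exactly matching one annotated exon) are
compared against cassette exons on exon length, flanking-intron lengths
and donor/acceptor scores, with pooled-variance t-tests and pairwise
exclusion of missing features, plus the count of exon keys shared by the
two groups.

## The synthetic-data generator

The generator emulates a two-group multi-sample short-read circRNA
experiment: one synthetic chromosome of protein-coding-like genes,
Ensembl-dialect exon annotation, a RepeatMasker-like BED track, and
per-sample CIRI2-dialect tables. Defaults describe the study conditions:
200 genes of 4–8 exons (80–400 nt each), half producing a circRNA, 8
samples per group with library sizes uniform in 0.8–1.2 × 2 × 10⁶ mappable
reads, planted |log2FC| = 2 on half of the circRNAs with 90% of the
differential ones upregulated, and negative-binomial counts (dispersion
0.1, the standard overdispersed RNA-seq choice; dispersion → 0 degenerates
to Poisson). Junction-count means are `base × 2^(log2FC·case) ×
lib/lib_ref` with base = 20 reads modulated per circRNA by a log2-normal
factor (σ = 1) for realistic spread; linear counts are drawn independently
(base 200), so circular–linear correlation is ~0 by construction.
Differential circRNAs and their signs are allocated *exactly* (rounded
counts via a seeded permutation) rather than by independent coin flips, so
the planted up-fraction is the configured one and direction summaries have
a fixed known truth.

Planted structure: circRNA loci are exonic at annotated boundaries (70%,
of which 40% single-exon), exonic with cryptic in-exon ends (10%),
intronic within the first or second intron (10%), exonic+intronic (10%),
plus intergenic circRNAs at 0.5% of loci to exercise the exclusion rule.
Introns flanking circularized exons are drawn from 2–20 kb, all others
from 200–2000 nt. Donor/acceptor consensus (CAG|GTAAGT, pyrimidine tract +
AG|G) is written at every annotated splice site with fixed GT/AG cores, so
a PWM trained on the annotation has genuine signal. Inverted 30-nt repeat
pairs (exact reverse complements at the default 100% identity; mutations
are sprinkled to hit lower identity targets; a `direct` orientation serves
as negative control) are planted in the two flanking introns of 60% of
fully exonic loci — only fully exonic loci, whose flanking introns are
unambiguous — together with occasional decoy repeats. UGCUU copies are
planted in the downstream 250-nt windows of half the exonic loci. A
fraction of exonic loci gains a second circRNA sharing its acceptor-side
end (multi-circRNA genes), exon-chain labels are emitted for multi-exon
circles, alternative exon-skipping transcripts are added to some
non-circRNA genes, and cassette exons with PSI values are drawn from
non-circRNA genes (hence zero overlap with circularized exons, matching
the designed truth).

Everything derives from one integer seed through a single generator; the
same seed yields byte-identical files. What the generator does *not*
emulate: read-level errors and mapping ambiguity, multi-chromosome
genomes, overlapping genes, non-canonical repeat families, expression-
dependent detection bias, and any correlation between circRNA levels and
host-gene expression. Passing tests therefore validate the analysis logic
and its statistical calibration, not the upstream detection step or the
full complexity of real annotation.

## Problem sizes and runtime

The test suite and the acceptance script use the default 200-gene,
8 + 8-sample dataset (~3.5 Mb genome, ~110 circRNAs) for locus-level
checks and dedicated 2,000-circRNA count-level simulations for statistical
calibration (type-I error within [0.035, 0.065]; ≥ 90% direction
recovery); these sizes give stable Monte-Carlo estimates while keeping a
full run to seconds on one CPU. Tier filtering is verified against a
brute-force rule evaluator on 200 random matrices (≤ 50 circRNAs × ≤ 10
samples), RCM detection against an independent Smith–Waterman
implementation on 100 random plantings, and motif counting against
exhaustive enumeration on 1,000 random sequences.

## Known limitations

- Internal circRNA structure is never inferred from reads; same-BSJ
  isoform groups exist only when an exon-chain table is supplied.
- The default splice-site scorer is annotation-trained per dataset, so
  absolute scores are not comparable across annotations (the
  background-equal zero anchor is).
- "Unannotated splice site" is defined relative to the supplied GTF; an
  incomplete annotation inflates the cryptic fraction.
- The t-test on untransformed RPM is the documented default; for strongly
  skewed data the log-transform flag is more appropriate.
- Gene-level linear expression for SCG/MCG correlations uses mean
  non-junction RPM at the circRNA's own locus, a proxy for full gene
  expression.
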