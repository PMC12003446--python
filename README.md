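# circkit

Post-detection analysis of circular RNA (circRNA) back-splice junction
calls: tiered confidence filtering, reads-per-million quantification,
differential abundance, structural and isoform classification, genomic
features of circRNA-producing loci, and splicing-factor motif profiling.

## Who this is for

circRNAs are covalently closed transcripts produced by *back-splicing*, in
which a downstream 5′ splice donor is joined to an upstream 3′ acceptor.
Detection tools such as CIRI2 turn RNA-seq alignments into per-sample
tables of candidate back-splice junctions (BSJs) with supporting read
counts. Everything a study does *after* detection — deciding which calls to
trust, normalizing, testing case-vs-control differences, classifying the
circles and characterizing the loci that produce them — is usually a pile
of one-off scripts. circkit packages that post-detection workflow as a
tested, seeded, reusable pipeline, with a synthetic-data generator that
plants known ground truth so every stage can be validated without any
external download.

## The model and statistics at the core

**Confidence tiers** on junction-read support, evaluated per circRNA over
the samples of the analysed set (independent predicates, not nested):

- *Tier 1* — ≥ 2 BSJ reads in ≥ 1 sample;
- *Tier 2* — present (count ≥ 1) in ≥ 2 samples with total reads ≥ 5
  (a per-sample variant, ≥ 5 reads in ≥ 2 samples, is available by flag);
- *Tier 3* — present in all or all-but-one samples, regardless of read
  number.

**Expression** of a circRNA in a sample is
`RPM = junction reads × 10⁶ / mappable reads`; linear host expression uses
non-junction reads identically. **Differential abundance** per circRNA is a
two-tailed two-sample t-test (Welch by default) on RPM values with
`log2FC = log2((mean_case + ε) / (mean_control + ε))`, ε = 0.01 RPM; a call
is *up* when log2FC ≥ 1 and p < 0.05, *down* when log2FC ≤ −1 and p < 0.05.
Up/down splits are compared with a Pearson chi-squared test, and
circular-vs-linear coupling with a Pearson R².

**Locus features.** Each BSJ end is classified against the annotation as an
annotated splice site, a cryptic exonic site (ie-BSJ) or a cryptic intronic
site (ii-BSJ, with the intron's ordinal), with the GT/AG dinucleotide check
of the would-be intron. Splice-site strength is a log-odds score over the
canonical 9-nt donor window (3 exonic + 6 intronic bases) and 23-nt
acceptor window (20 intronic + 3 exonic); the default scorer is a position
weight matrix estimated from all annotated splice sites of the supplied
GTF. Reverse complementary matches (RCMs) — inverted repeat pairs in the
two flanking introns that can base-pair and promote circularization — are
found by locally aligning (match +1, mismatch −1, gap −2) each upstream
repeat against the reverse complement of each downstream repeat, keeping
pairs with ≥ 20 aligned columns at ≥ 80% identity. MBNL1 (YGCY-class) and
CUGBP1 (UG-rich) motifs are counted with overlaps in the circularized exon
and the 250-nt flanking-intron windows.

## Worked example

Run the whole pipeline on a freshly simulated dataset (200 genes, half of
them circRNA-producing, 8 case + 8 control samples, planted |log2FC| = 2
with 90% of differential circRNAs upregulated):

```sh
circkit run-all --seed 1 --out demo
```

prints (from `demo/report.txt`):

```
circkit 0.1.0 pipeline report (seed 1)

circRNAs: 109 total; tiers 109/109/109 (1/2/3)
differential: 55 (50 up, 5 down, pct_up=90.91)
circ-linear R2: 0.003726
categories: {'exonic': 93, 'exonic+intronic': 10, 'intergenic': 1, 'intronic': 5}
length classes: {'1000-5000': 26, '200-1000': 36, '<200': 40, '>5000': 7}
SCG/MCG: 92% / 8%
flanking intron means: {'up': 9337.8..., 'down': 10476.5, 'other': 1880.8...}
RCM: 52 circRNAs with >=1 pair, 52 pairs
splice-site scores: donor 4.348, acceptor 5.982 (73.15% canonical GT/AG)
motif counts: {'CUGBP1:downstream_250': 107, ..., 'MBNL1:upstream_250': 465}
```

Reading it: all 109 simulated circRNAs survive every tier (counts are
deep); 55 are called differential and 90.9% of those are upregulated —
recovering the planted 90% — while the circular-linear R² near zero
reflects the independently drawn linear counts. The category and
length-class tables, the ~6× longer flanking introns, the 52/52 recovered
inverted-repeat pairs and the downstream-skewed motif counts all match the
planted ground truth recorded in `demo/dataset/truth_*.tsv`.

Each stage is also available separately (`circkit simulate`, `quantify`,
`structure`, `features`, `motifs`, `se-vs-ce`, `overlap`); see
`circkit COMMAND --help`.

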