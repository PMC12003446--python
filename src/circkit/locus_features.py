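"""Genomic features of circRNA-producing loci.

Covers four analyses of the introns and splice sites around back-splice
junctions:

* flanking-intron lengths (upstream/downstream in transcript orientation)
  against the host gene's other introns, with two-tailed t-tests;
* reverse-complementary-match (RCM) detection: every annotated repeat in the
  upstream flanking intron is locally aligned (Smith-Waterman scoring
  +1/-1/-2) against the reverse complement of every repeat in the downstream
  flanking intron; pairs passing a minimum alignment length and percent
  identity are inverted-repeat candidates that can base-pair across the
  intron pair and promote circularization;
* splice-site strength over the canonical windows — a 9-nt donor window
  (3 exonic + 6 intronic bases) and a 23-nt acceptor window (20 intronic +
  3 exonic bases), both in transcript orientation — scored with a pluggable
  log-odds model; the default is a position weight matrix estimated from all
  annotated splice sites of the supplied annotation with additive smoothing
  against genome base frequencies;
* BSJ end classification: each end is ``annotated`` (exact match to an
  annotated exon boundary), ``ie`` (inside an exon: a cryptic exonic site)
  or ``ii`` (inside an intron, with the intron's transcript-orientation
  ordinal recorded), plus the flanking dinucleotides of the would-be intron
  of the circularizing event and the canonical GT/AG flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats

from .io_formats import (
    CircRecord,
    GeneModel,
    GenomeAccessor,
    RepeatFeature,
    reverse_complement,
)

DONOR_EXONIC, DONOR_INTRONIC = 3, 6
ACCEPTOR_INTRONIC, ACCEPTOR_EXONIC = 20, 3
DONOR_LEN = DONOR_EXONIC + DONOR_INTRONIC  # 9
ACCEPTOR_LEN = ACCEPTOR_INTRONIC + ACCEPTOR_EXONIC  # 23


# ---------------------------------------------------------------------------
# host transcript and flanking introns
# ---------------------------------------------------------------------------

def select_host_transcript(circ: CircRecord, gene: GeneModel) -> str | None:
    """Longest transcript containing both BSJ ends; ties break on the
    lexicographically smallest transcript id; falls back to the longest
    transcript overlapping the circRNA at all."""

    def tx_span(tx: str) -> int:
        exons = gene.transcripts[tx]
        return exons[-1][1] - exons[0][0] + 1

    containing = [
        tx
        for tx in gene.transcripts
        if gene.transcripts[tx][0][0] <= circ.start
        and gene.transcripts[tx][-1][1] >= circ.end
    ]
    pool = containing or [
        tx
        for tx in gene.transcripts
        if gene.transcripts[tx][0][0] <= circ.end
        and gene.transcripts[tx][-1][1] >= circ.start
    ]
    if not pool:
        return None
    return min(pool, key=lambda tx: (-tx_span(tx), tx))


@dataclass
class IntronContext:
    circ_id: str
    gene_id: str
    transcript_id: str | None
    upstream: tuple[int, int] | None  # transcript orientation
    downstream: tuple[int, int] | None
    other_lengths: tuple[int, ...]
    no_host: bool = False

    @staticmethod
    def _length(iv: tuple[int, int] | None) -> int | None:
        return None if iv is None else iv[1] - iv[0] + 1

    @property
    def upstream_length(self) -> int | None:
        return self._length(self.upstream)

    @property
    def downstream_length(self) -> int | None:
        return self._length(self.downstream)


def extract_flanking_introns(
    circ: CircRecord, models: Mapping[str, GeneModel]
) -> IntronContext:
    """Locate the introns flanking a BSJ, in transcript orientation.

    The upstream intron is the nearest intron entirely 5' of the circRNA
    (transcript orientation) and the downstream intron the nearest entirely
    3'; a circRNA at the first/last exon gets a missing value on the absent
    side.  Remaining introns of the host transcript are the "other" control
    lengths.
    """
    gene = models.get(circ.gene_id)
    if gene is None:
        return IntronContext(circ.key, circ.gene_id, None, None, None, (), True)
    tx = select_host_transcript(circ, gene)
    if tx is None:
        return IntronContext(circ.key, gene.gene_id, None, None, None, (), True)
    introns = gene.introns(tx)  # genomic order
    left = [iv for iv in introns if iv[1] < circ.start]
    right = [iv for iv in introns if iv[0] > circ.end]
    g_left = left[-1] if left else None
    g_right = right[0] if right else None
    if gene.strand == "+":
        up, down = g_left, g_right
    else:
        up, down = g_right, g_left
    others = tuple(
        e - s + 1 for (s, e) in introns if (s, e) != g_left and (s, e) != g_right
    )
    return IntronContext(circ.key, gene.gene_id, tx, up, down, others)


@dataclass
class IntronComparison:
    group_means: dict
    group_sizes: dict
    p_up_vs_other: float | None
    p_down_vs_other: float | None


def compare_intron_features(
    contexts: Iterable[IntronContext],
    subsample_other: int | None = None,
    seed: int = 0,
) -> IntronComparison:
    """Flanking vs other intron lengths with two-tailed Student t-tests.

    ``subsample_other`` draws a seeded without-replacement control sample
    from the pooled other-intron lengths.  Zero-variance degenerate input is
    guarded: equal means give p = 1, unequal means p ~ 0 (a vanishing
    variance inflation keeps the statistic finite).
    """
    up, down, other = [], [], []
    for c in contexts:
        if c.upstream_length is not None:
            up.append(c.upstream_length)
        if c.downstream_length is not None:
            down.append(c.downstream_length)
        other.extend(c.other_lengths)
    if subsample_other is not None and len(other) > subsample_other:
        rng = np.random.default_rng(seed)
        other = list(rng.choice(other, size=subsample_other, replace=False))
    groups = {"up": up, "down": down, "other": other}
    means = {
        k: (float(np.mean(v)) if v else None) for k, v in groups.items()
    }
    sizes = {k: len(v) for k, v in groups.items()}

    def _t(a: list, b: list) -> float | None:
        if len(a) < 2 or len(b) < 2:
            return None
        res = stats.ttest_ind(a, b, equal_var=True)
        p = float(res.pvalue)
        if np.isnan(p):  # zero pooled variance
            return 1.0 if np.isclose(np.mean(a), np.mean(b)) else 0.0
        return p

    return IntronComparison(
        group_means=means,
        group_sizes=sizes,
        p_up_vs_other=_t(up, other),
        p_down_vs_other=_t(down, other),
    )


# ---------------------------------------------------------------------------
# RCM detection
# ---------------------------------------------------------------------------

@dataclass
class RCMPair:
    circ_id: str
    up_repeat: tuple[int, int]
    down_repeat: tuple[int, int]
    alignment_length: int
    percent_identity: float
    score: float


def _local_aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def find_rcms(
    context: IntronContext,
    repeats: Sequence[RepeatFeature],
    genome: GenomeAccessor,
    chrom: str,
    min_len: int = 20,
    min_ident: float = 80.0,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> list[RCMPair]:
    """Inverted-repeat (RCM) pairs between the two flanking introns.

    Each upstream-intron repeat is aligned locally against the reverse
    complement of each downstream-intron repeat, so only oppositely oriented
    (base-pairing-capable) sequence pairs can reach high identity; a pair is
    reported when the best local alignment spans >= ``min_len`` columns at
    >= ``min_ident`` percent identity.
    """
    if context.upstream is None or context.downstream is None:
        return []
    aligner = _local_aligner(match, mismatch, gap)

    def within(iv: tuple[int, int]) -> list[RepeatFeature]:
        return [
            r
            for r in repeats
            if r.chrom == chrom and r.start >= iv[0] and r.end <= iv[1]
        ]

    pairs: list[RCMPair] = []
    for ru in within(context.upstream):
        seq_u = genome.fetch(chrom, ru.start, ru.end, "+")
        for rd in within(context.downstream):
            seq_d_rc = reverse_complement(genome.fetch(chrom, rd.start, rd.end, "+"))
            alignments = aligner.align(seq_u, seq_d_rc)
            if len(alignments) == 0:
                continue
            best = alignments[0]
            c = best.counts()
            length = c.identities + c.mismatches + c.internal_gaps
            if length == 0:
                continue
            ident = 100.0 * c.identities / length
            if length >= min_len and ident >= min_ident:
                pairs.append(
                    RCMPair(
                        circ_id=context.circ_id,
                        up_repeat=(ru.start, ru.end),
                        down_repeat=(rd.start, rd.end),
                        alignment_length=int(length),
                        percent_identity=float(ident),
                        score=float(best.score),
                    )
                )
    pairs.sort(key=lambda p: (p.up_repeat, p.down_repeat))
    return pairs


# ---------------------------------------------------------------------------
# splice-site scoring
# ---------------------------------------------------------------------------

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


class PwmScorer:
    """First-order-free log-odds position weight matrix scorer.

    ``score(seq)`` returns the summed log2 odds of the sequence under the
    position probabilities against the background; a matrix whose position
    probabilities equal the background scores 0 for every sequence.
    Sequences of the wrong length or containing non-ACGT bases score None.
    """

    def __init__(
        self,
        donor_probs: np.ndarray,
        acceptor_probs: np.ndarray,
        background: Mapping[str, float],
    ) -> None:
        bg = np.array([background[b] for b in "ACGT"], dtype=float)
        bg = bg / bg.sum()
        self.background = bg
        self._donor = np.log2(donor_probs / bg[None, :])
        self._acceptor = np.log2(acceptor_probs / bg[None, :])

    @staticmethod
    def _score_matrix(matrix: np.ndarray, seq: str) -> float | None:
        seq = seq.upper().replace("U", "T")
        if len(seq) != matrix.shape[0]:
            return None
        total = 0.0
        for i, ch in enumerate(seq):
            k = _BASE_INDEX.get(ch)
            if k is None:
                return None
            total += matrix[i, k]
        return float(total)

    def score_donor(self, seq: str) -> float | None:
        return self._score_matrix(self._donor, seq)

    def score_acceptor(self, seq: str) -> float | None:
        return self._score_matrix(self._acceptor, seq)

    @classmethod
    def from_annotation(
        cls,
        models: Mapping[str, GeneModel],
        genome: GenomeAccessor,
        pseudocount: float = 1.0,
    ) -> "PwmScorer":
        """Estimate donor/acceptor matrices from every annotated splice site."""
        donor_counts = np.zeros((DONOR_LEN, 4))
        acceptor_counts = np.zeros((ACCEPTOR_LEN, 4))
        for gene in models.values():
            for tx in gene.transcripts:
                for intron in gene.introns(tx):
                    d = donor_window_seq(genome, gene.chrom, gene.strand, intron)
                    a = acceptor_window_seq(genome, gene.chrom, gene.strand, intron)
                    for seq, counts in ((d, donor_counts), (a, acceptor_counts)):
                        if seq is None or "N" in seq:
                            continue
                        for i, ch in enumerate(seq):
                            counts[i, _BASE_INDEX[ch]] += 1
        donor_probs = (donor_counts + pseudocount) / (
            donor_counts.sum(axis=1, keepdims=True) + 4 * pseudocount
        )
        acceptor_probs = (acceptor_counts + pseudocount) / (
            acceptor_counts.sum(axis=1, keepdims=True) + 4 * pseudocount
        )
        return cls(donor_probs, acceptor_probs, genome.base_frequencies())


def donor_window_seq(
    genome: GenomeAccessor, chrom: str, strand: str, intron: tuple[int, int]
) -> str | None:
    """9-nt donor window (3 exonic + 6 intronic) of an intron, transcript
    orientation.  The intron is given genomically; on the minus strand its
    donor sits at the genomic end."""
    s, e = intron
    try:
        if strand == "+":
            return genome.fetch(chrom, s - DONOR_EXONIC, s + DONOR_INTRONIC - 1, "+")
        return genome.fetch(chrom, e - DONOR_INTRONIC + 1, e + DONOR_EXONIC, "-")
    except (IndexError, KeyError):
        return None


def acceptor_window_seq(
    genome: GenomeAccessor, chrom: str, strand: str, intron: tuple[int, int]
) -> str | None:
    """23-nt acceptor window (20 intronic + 3 exonic), transcript orientation."""
    s, e = intron
    try:
        if strand == "+":
            return genome.fetch(
                chrom, e - ACCEPTOR_INTRONIC + 1, e + ACCEPTOR_EXONIC, "+"
            )
        return genome.fetch(
            chrom, s - ACCEPTOR_EXONIC, s + ACCEPTOR_INTRONIC - 1, "-"
        )
    except (IndexError, KeyError):
        return None


@dataclass
class SpliceSiteScores:
    circ_id: str
    donor_seq: str | None
    acceptor_seq: str | None
    donor_score: float | None
    acceptor_score: float | None


def score_splice_sites(
    circ: CircRecord,
    genome: GenomeAccessor,
    scorer: PwmScorer,
) -> SpliceSiteScores:
    """Score the back-splice's own would-be splice sites.

    The circularizing event treats the BSJ donor-side end as an exon end
    (donor window 3 bases in + 6 bases out) and the acceptor-side end as an
    exon start (acceptor window 20 bases out + 3 bases in), in transcript
    orientation.  The "intron" of that event is the genomic flank outside
    the circRNA.
    """
    # the would-be intron downstream of the donor / upstream of the acceptor
    if circ.strand == "+":
        donor_intron = (circ.end + 1, circ.end + DONOR_INTRONIC)
        acceptor_intron = (circ.start - ACCEPTOR_INTRONIC, circ.start - 1)
    else:
        donor_intron = (circ.start - DONOR_INTRONIC, circ.start - 1)
        acceptor_intron = (circ.end + 1, circ.end + ACCEPTOR_INTRONIC)
    d = donor_window_seq(genome, circ.chrom, circ.strand, donor_intron)
    a = acceptor_window_seq(genome, circ.chrom, circ.strand, acceptor_intron)
    return SpliceSiteScores(
        circ_id=circ.key,
        donor_seq=d,
        acceptor_seq=a,
        donor_score=scorer.score_donor(d) if d else None,
        acceptor_score=scorer.score_acceptor(a) if a else None,
    )


# ---------------------------------------------------------------------------
# BSJ end classification
# ---------------------------------------------------------------------------

@dataclass
class BsjSiteCall:
    circ_id: str
    start_label: str  # annotated | ie | ii | intergenic
    end_label: str
    donor_dinucleotide: str | None
    acceptor_dinucleotide: str | None
    canonical: bool
    intron_index: int | None  # transcript-orientation ordinal, ii ends
    last_exon: bool


def classify_bsj_sites(
    circ: CircRecord,
    models: Mapping[str, GeneModel],
    genome: GenomeAccessor,
) -> BsjSiteCall:
    """Label each BSJ end as annotated / cryptic-exonic / cryptic-intronic.

    An end is ``annotated`` when it exactly matches an annotated exon
    boundary on its own side (start against exon starts, end against exon
    ends), ``ie`` when strictly inside an exon, ``ii`` when inside an
    intron (the transcript-orientation intron ordinal is recorded), and
    ``intergenic`` outside any gene.  Dinucleotides are read from the genome
    immediately outside the BSJ — the ends of the would-be intron of the
    circularizing event — and the canonical flag requires GT after the donor
    and AG before the acceptor on the transcript strand.
    """
    gene = models.get(circ.gene_id)

    def _label(pos: int, boundaries: set[int]) -> tuple[str, int | None, bool]:
        if gene is None:
            return "intergenic", None, False
        if pos in boundaries:
            return "annotated", None, _in_last_exon(pos)
        for s, e in gene.all_exons():
            if s <= pos <= e:
                return "ie", None, _in_last_exon(pos)
        if gene.contains(pos):
            for tx in sorted(gene.transcripts):
                for idx, iv in enumerate(gene.introns_tx_order(tx), start=1):
                    if iv[0] <= pos <= iv[1]:
                        return "ii", idx, False
            return "ii", None, False
        return "intergenic", None, False

    def _in_last_exon(pos: int) -> bool:
        for tx in gene.transcripts:
            last = gene.exons_tx_order(tx)[-1]
            if last[0] <= pos <= last[1]:
                return True
        return False

    start_label, start_idx, start_last = _label(
        circ.start, gene.exon_starts() if gene else set()
    )
    end_label, end_idx, end_last = _label(
        circ.end, gene.exon_ends() if gene else set()
    )

    # dinucleotides of the would-be intron outside the circle
    n = genome.length(circ.chrom)
    if circ.strand == "+":
        donor2 = (
            genome.fetch(circ.chrom, circ.end + 1, circ.end + 2, "+")
            if circ.end + 2 <= n
            else None
        )
        acceptor2 = (
            genome.fetch(circ.chrom, circ.start - 2, circ.start - 1, "+")
            if circ.start >= 3
            else None
        )
    else:
        donor2 = (
            genome.fetch(circ.chrom, circ.start - 2, circ.start - 1, "-")
            if circ.start >= 3
            else None
        )
        acceptor2 = (
            genome.fetch(circ.chrom, circ.end + 1, circ.end + 2, "-")
            if circ.end + 2 <= n
            else None
        )
    canonical = donor2 == "GT" and acceptor2 == "AG"
    intron_index = next(
        (i for i in (start_idx, end_idx) if i is not None), None
    )
    return BsjSiteCall(
        circ_id=circ.key,
        start_label=start_label,
        end_label=end_label,
        donor_dinucleotide=donor2,
        acceptor_dinucleotide=acceptor2,
        canonical=canonical,
        intron_index=intron_index,
        last_exon=start_last or end_last,
    )


def dinucleotide_frequency_table(calls: Iterable[BsjSiteCall]) -> pd.DataFrame:
    """Aggregate donor/acceptor dinucleotide counts (plain-text logo stand-in)."""
    rows = [
        (c.donor_dinucleotide or "NA", c.acceptor_dinucleotide or "NA")
        for c in calls
    ]
    df = pd.DataFrame(rows, columns=["donor", "acceptor"])
    out = df.groupby(["donor", "acceptor"]).size().rename("n").reset_index()
    out["pct"] = 100.0 * out["n"] / out["n"].sum()
    return out.sort_values(["donor", "acceptor"]).reset_index(drop=True)
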