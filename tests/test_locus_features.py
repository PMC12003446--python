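"""Flanking introns, RCM detection, splice-site scoring, BSJ end classes."""

from __future__ import annotations

import math

import numpy as np
import pytest

from circkit import io_formats, locus_features
from circkit.io_formats import RepeatFeature, reverse_complement, write_fasta
from circkit.locus_features import (
    IntronContext,
    PwmScorer,
    acceptor_window_seq,
    classify_bsj_sites,
    compare_intron_features,
    donor_window_seq,
    extract_flanking_introns,
    find_rcms,
    score_splice_sites,
)
from .conftest import make_circ


class TestExtractFlankingIntrons:
    def test_forced_plus_strand(self, toy_models):
        ctx = extract_flanking_introns(make_circ(201, 300), toy_models)
        assert ctx.upstream == (101, 200) and ctx.upstream_length == 100
        assert ctx.downstream == (301, 400) and ctx.downstream_length == 100
        assert ctx.other_lengths == ()

    def test_minus_strand_swaps_sides(self, toy_models):
        ctx = extract_flanking_introns(
            make_circ(801, 900, strand="-", gene_id="GMINUS"), toy_models
        )
        assert ctx.upstream == (901, 1000)
        assert ctx.downstream == (701, 800)

    def test_first_exon_has_missing_upstream(self, toy_models):
        ctx = extract_flanking_introns(make_circ(1, 100), toy_models)
        assert ctx.upstream is None and ctx.downstream == (101, 200)

    def test_unknown_gene_flagged(self, toy_models):
        ctx = extract_flanking_introns(
            make_circ(10, 20, gene_id="NOPE"), toy_models
        )
        assert ctx.no_host


def student_oracle(a, b):
    """Pooled-variance two-sample t-test, two-tailed, from the textbook formula."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return 2 * tdist.sf(abs(t), na + nb - 2)


def ctx_with(up_len=None, down_len=None, others=()):
    up = (1, up_len) if up_len else None
    down = (1, down_len) if down_len else None
    return IntronContext("c", "g", "t", up, down, tuple(others))


class TestCompareIntronFeatures:
    def test_identical_groups_give_p_one(self):
        ctxs = [ctx_with(up_len=10, others=[10]) for _ in range(3)]
        cmp = compare_intron_features(ctxs)
        assert cmp.p_up_vs_other == pytest.approx(1.0)

    def test_student_p_matches_closed_form(self):
        ups = [10, 11, 9]
        others = [20, 21, 19]
        ctxs = [ctx_with(up_len=u, others=[o]) for u, o in zip(ups, others)]
        cmp = compare_intron_features(ctxs)
        assert cmp.p_up_vs_other == pytest.approx(student_oracle(ups, others), rel=1e-12)

    def test_seeded_subsampling_is_deterministic(self):
        ctxs = [ctx_with(up_len=i + 10, others=range(1, 30)) for i in range(4)]
        a = compare_intron_features(ctxs, subsample_other=10, seed=5)
        b = compare_intron_features(ctxs, subsample_other=10, seed=5)
        assert a.group_means["other"] == b.group_means["other"]
        assert a.group_sizes["other"] == 10


# ---------------------------------------------------------------------------
# RCM detection
# ---------------------------------------------------------------------------

def sw_oracle(a: str, b: str, match=1, mismatch=-1, gap=-2):
    """Independent Smith-Waterman DP with traceback (diagonal preferred).

    Returns (alignment_length, identities) of the first optimal local
    alignment, or (0, 0) when the best score is 0.
    """
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = H[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            H[i, j] = max(0, diag, H[i - 1, j] + gap, H[i, j - 1] + gap)
    best = H.max()
    if best == 0:
        return 0, 0
    i, j = np.unravel_index(np.argmax(H), H.shape)
    length = ident = 0
    while i > 0 and j > 0 and H[i, j] > 0:
        diag = H[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
        if H[i, j] == diag:
            length += 1
            ident += a[i - 1] == b[j - 1]
            i, j = i - 1, j - 1
        elif H[i, j] == H[i - 1, j] + gap:
            length += 1
            i -= 1
        else:
            length += 1
            j -= 1
    return length, ident


def plant_intron_pair(rng, orientation="inverted", rep_len=30, intron_len=3000):
    """Two random introns with one repeat planted in each; returns
    (sequence, up-intron interval, down-intron interval, repeat features)."""
    seq = list(rng.choice(list("ACGT"), size=2 * intron_len + 200))
    up = (101, 100 + intron_len)
    down = (up[1] + 1, up[1] + intron_len)
    core = "".join(rng.choice(list("ACGT"), size=rep_len))
    partner = reverse_complement(core) if orientation == "inverted" else core
    u0 = up[0] + int(rng.integers(50, intron_len - rep_len - 50))
    d0 = down[0] + int(rng.integers(50, intron_len - rep_len - 50))
    seq[u0 - 1 : u0 - 1 + rep_len] = list(core)
    seq[d0 - 1 : d0 - 1 + rep_len] = list(partner)
    repeats = [
        RepeatFeature("chrR", u0, u0 + rep_len - 1, "+", "AluSyn"),
        RepeatFeature("chrR", d0, d0 + rep_len - 1, "-", "AluSyn"),
    ]
    return "".join(seq), up, down, repeats


class TestFindRcms:
    def genome_for(self, tmp_path, seq):
        write_fasta({"chrR": seq}, tmp_path / "g.fa")
        return io_formats.read_genome(tmp_path / "g.fa")

    def test_no_repeats_gives_empty(self, tmp_path):
        rng = np.random.default_rng(0)
        seq, up, down, _ = plant_intron_pair(rng)
        genome = self.genome_for(tmp_path, seq)
        ctx = IntronContext("c", "g", "t", up, down, ())
        assert find_rcms(ctx, [], genome, "chrR") == []

    def test_planted_inverted_pair_found_exactly(self, tmp_path):
        rng = np.random.default_rng(1)
        seq, up, down, repeats = plant_intron_pair(rng)
        genome = self.genome_for(tmp_path, seq)
        ctx = IntronContext("c", "g", "t", up, down, ())
        (pair,) = find_rcms(ctx, repeats, genome, "chrR")
        assert pair.alignment_length == 30
        assert pair.percent_identity == 100.0

    def test_co_oriented_planting_yields_nothing(self, tmp_path):
        rng = np.random.default_rng(2)
        seq, up, down, repeats = plant_intron_pair(rng, orientation="direct")
        genome = self.genome_for(tmp_path, seq)
        ctx = IntronContext("c", "g", "t", up, down, ())
        assert find_rcms(ctx, repeats, genome, "chrR") == []

    def test_agrees_with_all_pairs_alignment_oracle(self, tmp_path):
        rng = np.random.default_rng(3)
        for trial in range(20):
            orientation = "inverted" if trial % 2 == 0 else "direct"
            seq, up, down, repeats = plant_intron_pair(
                rng, orientation=orientation, intron_len=2000
            )
            genome = self.genome_for(tmp_path, seq)
            ctx = IntronContext("c", "g", "t", up, down, ())
            got = {
                (p.up_repeat, p.down_repeat)
                for p in find_rcms(ctx, repeats, genome, "chrR")
            }
            expect = set()
            ups = [r for r in repeats if up[0] <= r.start and r.end <= up[1]]
            downs = [r for r in repeats if down[0] <= r.start and r.end <= down[1]]
            for ru in ups:
                for rd in downs:
                    a = genome.fetch("chrR", ru.start, ru.end, "+")
                    b = reverse_complement(
                        genome.fetch("chrR", rd.start, rd.end, "+")
                    )
                    length, ident = sw_oracle(a, b)
                    if length >= 20 and 100.0 * ident / length >= 80.0:
                        expect.add(
                            ((ru.start, ru.end), (rd.start, rd.end))
                        )
            assert got == expect


# ---------------------------------------------------------------------------
# splice-site scoring
# ---------------------------------------------------------------------------

class TestSpliceWindows:
    @pytest.fixture()
    def genome(self, tmp_path):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), size=600))
        write_fasta({"chrW": seq}, tmp_path / "w.fa")
        return io_formats.read_genome(tmp_path / "w.fa"), seq

    def test_donor_window_geometry_plus(self, genome):
        acc, seq = genome
        # exon ends at 100, intron [101, 200]: window = [98, 106]
        w = donor_window_seq(acc, "chrW", "+", (101, 200))
        assert w == seq[97:106]
        assert len(w) == 9

    def test_acceptor_window_geometry_plus(self, genome):
        acc, seq = genome
        # intron [101, 200], exon starts 201: window = [181, 203]
        w = acceptor_window_seq(acc, "chrW", "+", (101, 200))
        assert w == seq[180:203]
        assert len(w) == 23

    def test_window_geometry_minus(self, genome):
        acc, seq = genome
        # minus strand: donor at intron genomic end, acceptor at its start
        d = donor_window_seq(acc, "chrW", "-", (101, 200))
        assert d == reverse_complement(seq[194:203])
        a = acceptor_window_seq(acc, "chrW", "-", (101, 200))
        assert a == reverse_complement(seq[97:120])

    def test_window_past_contig_end_is_missing(self, genome):
        acc, _ = genome
        assert donor_window_seq(acc, "chrW", "+", (599, 600)) is None

    def test_uniform_pwm_scores_zero(self):
        bg = {b: 0.25 for b in "ACGT"}
        probs9 = np.full((9, 4), 0.25)
        probs23 = np.full((23, 4), 0.25)
        scorer = PwmScorer(probs9, probs23, bg)
        assert scorer.score_donor("ACGTACGTA") == pytest.approx(0.0)
        assert scorer.score_acceptor("A" * 23) == pytest.approx(0.0)

    def test_toy_pwm_consensus_score_by_hand(self):
        # two informative positions, 0.7 on consensus A, uniform background
        probs9 = np.full((9, 4), 0.25)
        probs9[0] = [0.7, 0.1, 0.1, 0.1]
        probs9[1] = [0.7, 0.1, 0.1, 0.1]
        scorer = PwmScorer(probs9, np.full((23, 4), 0.25), {b: 0.25 for b in "ACGT"})
        expected = 2 * math.log2(0.7 / 0.25)
        assert scorer.score_donor("AACGTACGT") == pytest.approx(expected)

    def test_n_base_scores_missing(self):
        scorer = PwmScorer(
            np.full((9, 4), 0.25), np.full((23, 4), 0.25), {b: 0.25 for b in "ACGT"}
        )
        assert scorer.score_donor("ACGTNCGTA") is None

    def test_annotated_donors_outscore_random_9mers(
        self, dataset_models, dataset_genome
    ):
        """Direction sanity: the trained PWM prefers real donor windows."""
        scorer = PwmScorer.from_annotation(dataset_models, dataset_genome)
        donor_scores = []
        for gene in list(dataset_models.values())[:50]:
            for tx in gene.transcripts:
                for intron in gene.introns(tx):
                    w = donor_window_seq(
                        dataset_genome, gene.chrom, gene.strand, intron
                    )
                    s = scorer.score_donor(w) if w else None
                    if s is not None:
                        donor_scores.append(s)
        rng = np.random.default_rng(11)
        n = dataset_genome.length("chr1")
        random_scores = []
        for _ in range(300):
            p = int(rng.integers(1, n - 9))
            s = scorer.score_donor(dataset_genome.fetch("chr1", p, p + 8))
            if s is not None:
                random_scores.append(s)
        assert np.mean(donor_scores) > np.mean(random_scores) + 2.0


class TestClassifyBsjSites:
    @pytest.fixture()
    def toy_genome(self, tmp_path):
        # deterministic sequence with GT/AG planted at the toy introns
        rng = np.random.default_rng(13)
        seq = list(rng.choice(list("ACGT"), size=1300))
        for intron in [(101, 200), (301, 400)]:  # GPLUS, + strand
            seq[intron[0] - 1 : intron[0] + 1] = list("GT")
            seq[intron[1] - 2 : intron[1]] = list("AG")
        for intron in [(701, 800), (901, 1000)]:  # GMINUS: revcomp signals
            seq[intron[1] - 2 : intron[1]] = list("AC")  # GT on minus strand
            seq[intron[0] - 1 : intron[0] + 1] = list("CT")  # AG on minus strand
        write_fasta({"chrT": "".join(seq)}, tmp_path / "t.fa")
        return io_formats.read_genome(tmp_path / "t.fa")

    def test_annotated_ends_with_canonical_dinucleotides(
        self, toy_models, toy_genome
    ):
        call = classify_bsj_sites(make_circ(201, 300), toy_models, toy_genome)
        assert (call.start_label, call.end_label) == ("annotated", "annotated")
        assert call.donor_dinucleotide == "GT"
        assert call.acceptor_dinucleotide == "AG"
        assert call.canonical

    def test_minus_strand_canonical(self, toy_models, toy_genome):
        call = classify_bsj_sites(
            make_circ(801, 900, strand="-", gene_id="GMINUS"), toy_models, toy_genome
        )
        assert call.canonical

    def test_cryptic_exonic_end_in_terminal_exon(self, toy_models, toy_genome):
        call = classify_bsj_sites(make_circ(201, 490), toy_models, toy_genome)
        assert call.end_label == "ie"
        assert call.last_exon

    def test_intronic_ends_carry_intron_index(self, toy_models, toy_genome):
        call = classify_bsj_sites(make_circ(310, 390), toy_models, toy_genome)
        assert (call.start_label, call.end_label) == ("ii", "ii")
        assert call.intron_index == 2

    def test_minus_strand_intron_index_counts_from_transcript_start(
        self, toy_models, toy_genome
    ):
        call = classify_bsj_sites(
            make_circ(910, 990, strand="-", gene_id="GMINUS"), toy_models, toy_genome
        )
        assert call.intron_index == 1


class TestScoreSpliceSites:
    def test_bsj_windows_read_the_flanks_outside_the_circle(self, tmp_path):
        seq = "".join(
            np.random.default_rng(17).choice(list("ACGT"), size=400)
        )
        write_fasta({"chrS": seq}, tmp_path / "s.fa")
        genome = io_formats.read_genome(tmp_path / "s.fa")
        probs9 = np.full((9, 4), 0.25)
        scorer = PwmScorer(probs9, np.full((23, 4), 0.25), {b: 0.25 for b in "ACGT"})
        circ = make_circ(101, 200, chrom="chrS")
        res = score_splice_sites(circ, genome, scorer)
        assert res.donor_seq == seq[197:206]  # 3 in + 6 out at the donor end
        assert res.acceptor_seq == seq[80:103]  # 20 out + 3 in at the acceptor
        assert res.donor_score == pytest.approx(0.0)
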