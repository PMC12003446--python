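"""Splicing-factor motif profiling around circularized exons.

MBNL1 and CUGBP1 are the two splicing factors whose dysregulation drives
the spliceopathy of myotonic dystrophy; their binding preferences are
described by short degenerate sequence motifs (MBNL1: YGCY-class 4-mers
plus the literal 5-mers UGCUU and GCUGC; CUGBP1: UG-rich).  This module
counts overlapping motif occurrences in three transcript-orientation
regions per circRNA — the circularized exon body and 250-nt windows in the
flanking introns immediately upstream and downstream — and compares
single-exon circRNAs against cassette exons on exon size, flanking-intron
length and splice-site strength.

Outputs are sequence-motif counts only; no claim of in vivo binding is
made.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CircRecord, GeneModel, GenomeAccessor
from .locus_features import (
    IntronContext,
    PwmScorer,
    acceptor_window_seq,
    donor_window_seq,
    extract_flanking_introns,
)

# IUPAC codes accepted in patterns; N in the *sequence* never matches
_IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "U": "T",
    "Y": "CT",
    "R": "AG",
}

REGIONS = ("exon_body", "upstream_250", "downstream_250")


@dataclass(frozen=True)
class MotifSet:
    """A named set of sequence patterns counted with overlaps allowed."""

    name: str
    patterns: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError("MotifSet needs at least one pattern")
        for p in self.patterns:
            for ch in p.upper():
                if ch not in _IUPAC:
                    raise ValueError(f"pattern {p!r}: unsupported symbol {ch!r}")


# YGCY is a 4-mer; the two literal 5-mers are counted alongside it (GCUGC
# does not itself match YGCY, so it is listed explicitly).
MBNL1_MOTIFS = MotifSet("MBNL1", ("YGCY", "UGCUU", "GCUGC"))
# UG-rich proxy: overlapping UGUG occurrences; see count_ug_runs for the
# run-based alternative.
CUGBP1_MOTIFS = MotifSet("CUGBP1", ("UGUG",))


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _pattern_matches(seq: str, pattern: str) -> int:
    pat = [_IUPAC[ch] for ch in pattern.upper()]
    m, n = len(pat), len(seq)
    count = 0
    for i in range(n - m + 1):
        if all(seq[i + k] in pat[k] for k in range(m)):
            count += 1
    return count


def count_motifs(sequence: str, motifs: MotifSet) -> dict[str, int]:
    """Overlapping sliding-window occurrence counts per pattern plus total.

    U and T are equivalent on both sides; N in the sequence never matches.
    The empty sequence yields zero counts.
    """
    seq = _normalize(sequence)
    counts = {p: _pattern_matches(seq, p) for p in motifs.patterns}
    counts["total"] = sum(counts.values())
    return counts


def count_ug_runs(sequence: str, min_units: int = 3) -> int:
    """Maximal (UG)n runs with n >= min_units — the run-based UG-rich counter."""
    seq = _normalize(sequence)
    runs = 0
    i = 0
    while i < len(seq) - 1:
        n = 0
        j = i
        while j + 1 < len(seq) and seq[j] == "T" and seq[j + 1] == "G":
            n += 1
            j += 2
        if n >= min_units:
            runs += 1
            i = j
        else:
            i += 1
    return runs


# ---------------------------------------------------------------------------
# region profiles
# ---------------------------------------------------------------------------

@dataclass
class MotifProfile:
    circ_id: str
    region: str
    counts: dict[str, dict[str, int]]  # motif set name -> pattern counts
    truncated: bool = False

    def total(self, set_name: str) -> int:
        return self.counts[set_name]["total"]


def _region_sequences(
    circ: CircRecord,
    context: IntronContext,
    genome: GenomeAccessor,
    window: int,
) -> dict[str, tuple[str, bool]]:
    """Extract the three analysis regions in transcript orientation.

    Windows are clipped at the flanking intron's far end (truncation
    flagged); a missing flanking intron yields an empty region.
    """
    chrom, strand = circ.chrom, circ.strand
    out: dict[str, tuple[str, bool]] = {
        "exon_body": (genome.fetch(chrom, circ.start, circ.end, strand), False)
    }
    for region, intron in (
        ("upstream_250", context.upstream),
        ("downstream_250", context.downstream),
    ):
        if intron is None or window == 0:
            out[region] = ("", False)
            continue
        ilen = intron[1] - intron[0] + 1
        w = min(window, ilen)
        truncated = w < window
        # the window hugs the end of the intron adjacent to the circRNA
        upstream = region == "upstream_250"
        if (strand == "+") == upstream:
            g = (intron[1] - w + 1, intron[1])
        else:
            g = (intron[0], intron[0] + w - 1)
        out[region] = (genome.fetch(chrom, g[0], g[1], strand), truncated)
    return out


def profile_regions(
    circs: Iterable[CircRecord],
    models: Mapping[str, GeneModel],
    genome: GenomeAccessor,
    motif_sets: Sequence[MotifSet] = (MBNL1_MOTIFS, CUGBP1_MOTIFS),
    window: int = 250,
) -> list[MotifProfile]:
    """Per-circRNA motif counts in the exon body and both intronic windows."""
    profiles: list[MotifProfile] = []
    for circ in circs:
        context = extract_flanking_introns(circ, models)
        regions = _region_sequences(circ, context, genome, window)
        for region in REGIONS:
            if window == 0 and region != "exon_body":
                continue
            seq, truncated = regions[region]
            profiles.append(
                MotifProfile(
                    circ_id=circ.key,
                    region=region,
                    counts={ms.name: count_motifs(seq, ms) for ms in motif_sets},
                    truncated=truncated,
                )
            )
    return profiles


def region_summary(
    profiles: Iterable[MotifProfile], set_names: Sequence[str] = ("MBNL1", "CUGBP1")
) -> pd.DataFrame:
    """Aggregate total motif counts per region per motif set."""
    rows = []
    for p in profiles:
        for name in set_names:
            rows.append({"region": p.region, "motif_set": name, "n": p.total(name)})
    df = pd.DataFrame(rows)
    return (
        df.groupby(["motif_set", "region"])["n"].sum().rename("total").reset_index()
    )


# ---------------------------------------------------------------------------
# single-exon circRNAs vs cassette exons
# ---------------------------------------------------------------------------

def read_cassette_exons(path) -> pd.DataFrame:
    """Cassette-exon TSV: gene_id, chrom, start, end, strand [, psi, direction]."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    if "psi" in df.columns:
        bad = df["psi"].dropna()
        if ((bad < 0) | (bad > 100)).any():
            raise ValueError(f"{path}: psi outside [0, 100]")
    return df


def exon_feature_table(
    exons: pd.DataFrame,
    models: Mapping[str, GeneModel],
    genome: GenomeAccessor,
    scorer: PwmScorer,
) -> pd.DataFrame:
    """Feature table (exon length, flanking intron lengths, splice-site
    scores) for a frame of exon intervals with gene_id/chrom/start/end/strand."""
    rows = []
    for r in exons.itertuples(index=False):
        rec = CircRecord(
            circ_id=f"{r.chrom}:{r.start}|{r.end}",
            chrom=r.chrom,
            start=int(r.start),
            end=int(r.end),
            strand=r.strand,
            junction_reads=0,
            non_junction_reads=0,
            reported_type="exon",
            gene_id=r.gene_id,
            sample_id="",
        )
        ctx = extract_flanking_introns(rec, models)
        donor = acceptor = None
        if ctx.downstream is not None:
            # donor of the exon feeds the downstream intron
            seq = donor_window_seq(genome, r.chrom, r.strand, _genomic(ctx.downstream))
            donor = scorer.score_donor(seq) if seq else None
        if ctx.upstream is not None:
            seq = acceptor_window_seq(genome, r.chrom, r.strand, _genomic(ctx.upstream))
            acceptor = scorer.score_acceptor(seq) if seq else None
        rows.append(
            {
                "key": rec.circ_id,
                "gene_id": r.gene_id,
                "exon_length": rec.genomic_span,
                "upstream_intron_length": ctx.upstream_length,
                "downstream_intron_length": ctx.downstream_length,
                "donor_score": donor,
                "acceptor_score": acceptor,
            }
        )
    return pd.DataFrame(rows)


def _genomic(iv: tuple[int, int]) -> tuple[int, int]:
    return iv


FEATURES = (
    "exon_length",
    "upstream_intron_length",
    "downstream_intron_length",
    "donor_score",
    "acceptor_score",
)


@dataclass
class SeVsCeResult:
    table: pd.DataFrame
    overlap_count: int


def compare_se_vs_ce(
    se_features: pd.DataFrame, ce_features: pd.DataFrame
) -> SeVsCeResult:
    """Compare single-exon circRNA exons against cassette exons.

    Per feature: group means and a two-tailed pooled-variance Student
    t-test; entries missing a feature are excluded pairwise from that
    feature's test.  The overlap count is the number of exon keys present
    in both groups (the analysis that found zero shared exons between
    circularized and mis-spliced cassette exons).
    """
    if not len(se_features) or not len(ce_features):
        raise ValueError("both feature tables must be nonempty")
    rows = []
    for feat in FEATURES:
        a = se_features[feat].dropna().to_numpy(dtype=float)
        b = ce_features[feat].dropna().to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            rows.append(
                {
                    "feature": feat,
                    "mean_se_circ": float(np.mean(a)) if len(a) else None,
                    "mean_ce": float(np.mean(b)) if len(b) else None,
                    "n_se_circ": len(a),
                    "n_ce": len(b),
                    "p_value": None,
                }
            )
            continue
        res = stats.ttest_ind(a, b, equal_var=True)
        p = float(res.pvalue)
        if np.isnan(p):
            p = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
        rows.append(
            {
                "feature": feat,
                "mean_se_circ": float(a.mean()),
                "mean_ce": float(b.mean()),
                "n_se_circ": len(a),
                "n_ce": len(b),
                "p_value": p,
            }
        )
    overlap = len(set(se_features["key"]) & set(ce_features["key"]))
    return SeVsCeResult(table=pd.DataFrame(rows), overlap_count=overlap)
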