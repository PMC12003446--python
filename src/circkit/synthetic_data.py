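"""Fully seeded synthetic dataset generator with a planted truth manifest.

The generator emulates a two-group (case vs control) multi-sample circRNA
experiment of the kind produced by rRNA-depleted short-read RNA-seq followed
by a BSJ caller: a fake genome, Ensembl-dialect exon annotation, a
RepeatMasker-like BED track, and per-sample CIRI2-dialect call tables.

Planted ground truth covers every downstream analysis:

* circRNA loci of known structural category (exonic at annotated boundaries,
  exonic with cryptic in-exon ends, intronic, exonic+intronic, intergenic);
* long flanking introns around circularized exons (short introns elsewhere);
* inverted repeat pairs (reverse-complementary matches) in the two flanking
  introns of a configurable fraction of loci, annotated in the BED track;
* splicing-factor motif copies written into the 250-nt intronic windows
  adjacent to circularized exons;
* negative-binomial junction read counts with a planted log2 fold change for
  a subset of circRNAs, plus independent linear (non-junction) counts.

Everything is driven by one integer seed; the same seed reproduces the same
files byte for byte.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    CircRecord,
    RepeatFeature,
    circ_key,
    reverse_complement,
    write_bed,
    write_ciri_table,
    write_fasta,
    write_tsv,
)

_BASES = np.array(list("ACGT"))
_PURINES = np.array(list("AG"))
_PYRIMIDINES = np.array(list("CT"))

CHROM = "chr1"


class ConfigError(ValueError):
    """The simulation geometry cannot be satisfied."""


@dataclass
class SimulationConfig:
    """Study conditions for the simulated experiment.

    Defaults describe a desk-scale two-group experiment: 200 genes of 4-8
    exons (80-400 nt) on one synthetic chromosome, half of them producing a
    circRNA, 8 samples per group, library sizes around 2 million mappable
    reads, planted |log2FC| = 2 with 90% of differential circRNAs
    upregulated, and negative-binomial counts with dispersion 0.1.
    Introns flanking circularized exons are drawn from a long range
    (2-20 kb) and all other introns from a short range (200-2000 nt).
    """

    seed: int = 0
    n_genes: int = 200
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_length: tuple[int, int] = (80, 400)
    intron_length_flanking: tuple[int, int] = (2000, 20000)
    intron_length_other: tuple[int, int] = (200, 2000)
    intergenic_gap: tuple[int, int] = (500, 2000)
    n_samples_per_group: int = 8
    frac_circ_genes: float = 0.5
    frac_multi_circ: float = 0.3
    frac_single_exon: float = 0.4
    frac_differential: float = 0.5
    planted_log2fc: float = 2.0
    frac_upregulated: float = 0.9
    frac_intergenic: float = 0.005
    nb_dispersion: float = 0.1
    base_mean_junction_reads: float = 20.0
    base_mean_log2_sigma: float = 1.0
    linear_base_mean: float = 200.0
    library_size: int = 2_000_000
    # category mix among circRNA loci (exonic_partial = exonic category with
    # cryptic in-exon BSJ ends)
    category_mix: dict = field(
        default_factory=lambda: {
            "exonic": 0.7,
            "exonic_partial": 0.1,
            "intronic": 0.1,
            "exonic+intronic": 0.1,
        }
    )
    # inverted-repeat planting
    frac_rcm_loci: float = 0.6
    repeat_length: int = 30
    repeat_identity: float = 1.0
    repeat_orientation: str = "inverted"  # or "direct" (negative control)
    # motif planting: (pattern in RNA alphabet, region, copies per locus)
    motif_plant: list = field(
        default_factory=lambda: [("UGCUU", "downstream_250", 3)]
    )
    frac_motif_loci: float = 0.5
    frac_alt_transcript: float = 0.2
    n_cassette_exons: int = 30

    def validate(self) -> None:
        for name in (
            "frac_circ_genes",
            "frac_multi_circ",
            "frac_single_exon",
            "frac_differential",
            "frac_upregulated",
            "frac_intergenic",
            "frac_rcm_loci",
            "frac_motif_loci",
            "frac_alt_transcript",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        for name in (
            "exons_per_gene",
            "exon_length",
            "intron_length_flanking",
            "intron_length_other",
            "intergenic_gap",
        ):
            lo, hi = getattr(self, name)
            if lo > hi or lo <= 0:
                raise ConfigError(f"{name}=({lo},{hi}) is not a valid range")
        if self.exons_per_gene[0] < 3:
            raise ConfigError("genes need >= 3 exons to host internal circRNAs")
        if self.library_size <= 0:
            raise ConfigError("library_size must be positive")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        margin = 2 * (self.repeat_length + 600)
        if self.intron_length_flanking[0] < margin:
            raise ConfigError(
                f"flanking introns ({self.intron_length_flanking[0]} nt) too "
                f"short to hold planted repeats plus margins ({margin} nt)"
            )
        if self.repeat_orientation not in {"inverted", "direct"}:
            raise ConfigError("repeat_orientation must be inverted or direct")


@dataclass
class TruthManifest:
    """Planted ground truth for every simulated feature."""

    circs: pd.DataFrame
    repeats: pd.DataFrame
    motifs: pd.DataFrame
    cassette_exons: pd.DataFrame
    chains: pd.DataFrame


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: dict
    gtf: pd.DataFrame
    repeats: list
    manifest: TruthManifest
    counts: pd.DataFrame
    linear: pd.DataFrame
    sample_sheet: pd.DataFrame
    paths: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def _realize_template(template: str, probs: list[float], rng) -> str:
    """Realize a consensus template (transcript orientation).

    ``Y`` draws a pyrimidine with the stated probability (else a purine);
    ``N`` keeps whatever random base is already in place (returned as ``N``
    and skipped by the writer); fixed letters are kept with the stated
    probability, else replaced by a uniform random base.
    """
    out = []
    for ch, p in zip(template, probs):
        if ch == "N":
            out.append("N")
        elif ch == "Y":
            out.append(
                rng.choice(_PYRIMIDINES) if rng.random() < p else rng.choice(_PURINES)
            )
        else:
            out.append(ch if rng.random() < p else rng.choice(_BASES))
    return "".join(out)


def _write_seq(arr: np.ndarray, g_start: int, tx_seq: str, strand: str) -> None:
    """Write ``tx_seq`` (transcript orientation) into the genomic window
    starting at 1-based ``g_start``; minus strand writes the reverse
    complement.  ``N`` positions are left untouched."""
    s = tx_seq if strand == "+" else reverse_complement(tx_seq)
    for i, ch in enumerate(s):
        if ch != "N":
            arr[g_start - 1 + i] = ch


_DONOR_TEMPLATE = "CAGGTAAGT"  # exon[-3:] + intron[:6]
_DONOR_PROBS = [0.85, 0.85, 0.85, 1.0, 1.0, 0.85, 0.85, 0.85, 0.85]
_ACCEPTOR_TEMPLATE = "Y" * 18 + "AG" + "GNN"  # intron[-20:] + exon[:3]
_ACCEPTOR_PROBS = [0.9] * 18 + [1.0, 1.0, 0.85, 0.0, 0.0]


def _plant_splice_consensus(arr, intron: tuple[int, int], strand: str, rng) -> None:
    """Write donor/acceptor consensus around one intron, in transcript
    orientation.  The donor 9-mer spans the last 3 exonic and first 6
    intronic bases; the acceptor 23-mer the last 20 intronic and first 3
    exonic bases."""
    s, e = intron
    donor = _realize_template(_DONOR_TEMPLATE, _DONOR_PROBS, rng)
    acceptor = _realize_template(_ACCEPTOR_TEMPLATE, _ACCEPTOR_PROBS, rng)
    if strand == "+":
        _write_seq(arr, s - 3, donor, "+")
        _write_seq(arr, e - 19, acceptor, "+")
    else:
        # donor site sits at the intron's genomic end, acceptor at its start
        _write_seq(arr, e - 5, donor, "-")
        _write_seq(arr, s - 3, acceptor, "-")


def rna_to_dna(pattern: str) -> str:
    return pattern.upper().replace("U", "T")


# ---------------------------------------------------------------------------
# locus construction
# ---------------------------------------------------------------------------

def build_locus_set(config: SimulationConfig):
    """Build the genome, annotation, repeat track and truth manifest.

    Returns ``(genome, gtf, repeats, manifest)`` where ``genome`` maps
    chromosome name to sequence, ``gtf`` is a DataFrame of exon features and
    ``repeats`` a list of :class:`RepeatFeature`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_genes = config.n_genes
    n_circ = int(round(config.frac_circ_genes * n_genes))
    circ_gene_idx = set(rng.permutation(n_genes)[:n_circ].tolist())

    # category per circ gene, honoring the configured mix
    cats = list(config.category_mix)
    weights = np.array([config.category_mix[c] for c in cats], dtype=float)
    weights = weights / weights.sum()
    cat_pool = [cats[i] for i in rng.choice(len(cats), size=n_circ, p=weights)]

    genes: list[dict] = []
    cursor = 1001  # leading pad
    ci = 0
    el_lo, el_hi = config.exon_length
    il_lo, il_hi = config.intron_length_other
    fl_lo, fl_hi = config.intron_length_flanking

    for g in range(n_genes):
        gene_id = f"G{g + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = rng.integers(el_lo, el_hi + 1, size=n_ex)
        intron_lens = rng.integers(il_lo, il_hi + 1, size=n_ex - 1)
        is_circ = g in circ_gene_idx
        category = cat_pool[ci] if is_circ else None
        plan: dict = {"category": category}
        if is_circ:
            ci += 1
            if category in ("exonic", "exonic_partial"):
                i = int(rng.integers(2, n_ex))  # internal exon, genomic ordinal
                if category == "exonic_partial" or rng.random() < config.frac_single_exon:
                    j = i
                else:
                    j = min(n_ex - 1, i + int(rng.integers(1, 3)))
                plan.update(i=i, j=j)
                intron_lens[i - 2] = rng.integers(fl_lo, fl_hi + 1)
                intron_lens[j - 1] = rng.integers(fl_lo, fl_hi + 1)
            elif category == "intronic":
                k_tx = int(rng.integers(1, 3))  # first or second intron
                k_g = k_tx if strand == "+" else (n_ex - 1) - k_tx + 1
                plan.update(k_tx=k_tx, k_g=k_g)
                intron_lens[k_g - 1] = rng.integers(fl_lo, fl_hi + 1)
            else:  # exonic+intronic
                i = int(rng.integers(2, n_ex))
                plan.update(i=i)
                intron_lens[i - 2] = rng.integers(fl_lo, fl_hi + 1)
                intron_lens[i - 1] = rng.integers(fl_lo, fl_hi + 1)
        # absolute placement
        start = cursor
        exons, introns = [], []
        pos = start
        for k in range(n_ex):
            exons.append((pos, pos + int(exon_lens[k]) - 1))
            pos += int(exon_lens[k])
            if k < n_ex - 1:
                introns.append((pos, pos + int(intron_lens[k]) - 1))
                pos += int(intron_lens[k])
        gene_end = pos - 1
        genes.append(
            {
                "gene_id": gene_id,
                "strand": strand,
                "n_ex": n_ex,
                "exons": exons,
                "introns": introns,
                "span": (start, gene_end),
                "is_circ": is_circ,
                "plan": plan,
                "gap_after": (gene_end + 1, gene_end + int(rng.integers(*config.intergenic_gap))),
            }
        )
        cursor = genes[-1]["gap_after"][1] + 1

    total_len = cursor + 1000

    # --- plant circRNAs ---------------------------------------------------
    circ_rows: list[dict] = []
    for gene in genes:
        if not gene["is_circ"]:
            continue
        strand = gene["strand"]
        exons, introns = gene["exons"], gene["introns"]
        n_ex = gene["n_ex"]
        plan = gene["plan"]
        cat = plan["category"]
        if cat in ("exonic", "exonic_partial"):
            i, j = plan["i"], plan["j"]
            up_g, down_g = introns[i - 2], introns[j - 1]
            if cat == "exonic":
                start, end = exons[i - 1][0], exons[j - 1][1]
                labels = ("annotated", "annotated")
            else:
                es, ee = exons[i - 1]
                L = ee - es + 1
                a = int(rng.integers(5, L - 20))
                b = int(rng.integers(a + 10, L - 5))
                start, end = es + a, es + b
                labels = ("ie", "ie")
            row_cat = "exonic"
            intron_index = 0
            exon_span = (i, j)
        elif cat == "intronic":
            k_g, k_tx = plan["k_g"], plan["k_tx"]
            s, e = introns[k_g - 1]
            a = int(rng.integers(s + 25, s + (e - s) // 2))
            start = a
            end = a + int(rng.integers(60, 401))
            labels = ("ii", "ii")
            row_cat = "intronic"
            intron_index = k_tx
            up_g = down_g = None
            exon_span = (0, 0)
        else:  # exonic+intronic
            i = plan["i"]
            start = exons[i - 1][0]
            s, e = introns[i - 1]
            end = s + int(rng.integers(60, 1001))
            labels = ("annotated", "ii")
            row_cat = "exonic+intronic"
            k_g = i
            intron_index = k_g if strand == "+" else (n_ex - 1) - k_g + 1
            up_g, down_g = introns[i - 2], introns[i - 1]
            exon_span = (i, i)
        circ_rows.append(
            {
                "gene": gene,
                "start": start,
                "end": end,
                "category": row_cat,
                "start_label": labels[0],
                "end_label": labels[1],
                "intron_index": intron_index,
                "up_g": up_g,
                "down_g": down_g,
                "exon_span": exon_span,
                "is_extra": False,
            }
        )
        # extra circRNAs for multi-circRNA genes: shared acceptor-side end,
        # different donor-side exon boundary
        if (
            cat == "exonic"
            and plan["j"] < n_ex - 1
            and rng.random() < config.frac_multi_circ
        ):
            j2 = plan["j"] + 1
            circ_rows.append(
                {
                    "gene": gene,
                    "start": exons[plan["i"] - 1][0],
                    "end": exons[j2 - 1][1],
                    "category": "exonic",
                    "start_label": "annotated",
                    "end_label": "annotated",
                    "intron_index": 0,
                    "up_g": introns[plan["i"] - 2],
                    "down_g": introns[j2 - 1],
                    "exon_span": (plan["i"], j2),
                    "is_extra": True,
                }
            )

    # intergenic circRNAs in gaps between genes
    n_intergenic = int(round(config.frac_intergenic * len(circ_rows)))
    if config.frac_intergenic > 0 and circ_rows:
        n_intergenic = max(1, n_intergenic)
    gap_pool = [g["gap_after"] for g in genes if g["gap_after"][1] - g["gap_after"][0] >= 300]
    picks = rng.choice(len(gap_pool), size=min(n_intergenic, len(gap_pool)), replace=False)
    for p in np.sort(picks):
        gs, ge = gap_pool[int(p)]
        start = gs + int(rng.integers(50, (ge - gs) // 2))
        end = start + int(rng.integers(60, 201))
        circ_rows.append(
            {
                "gene": None,
                "start": start,
                "end": min(end, ge - 50),
                "category": "intergenic",
                "start_label": "intergenic",
                "end_label": "intergenic",
                "intron_index": 0,
                "up_g": None,
                "down_g": None,
                "exon_span": (0, 0),
                "is_extra": False,
            }
        )

    # --- genome sequence ---------------------------------------------------
    arr = _BASES[rng.integers(0, 4, size=total_len)].copy()
    for gene in genes:
        for intron in gene["introns"]:
            _plant_splice_consensus(arr, intron, gene["strand"], rng)

    # --- repeats (RCM pairs + decoys) --------------------------------------
    repeat_feats: list[RepeatFeature] = []
    repeat_rows: list[dict] = []
    L = config.repeat_length
    for row in circ_rows:
        # only fully exonic loci: their flanking introns are exactly the
        # planted long introns, so pair recovery has unambiguous truth
        if row["is_extra"] or row["category"] != "exonic" or row["up_g"] is None:
            row["has_rcm"] = False
            continue
        if rng.random() >= config.frac_rcm_loci:
            row["has_rcm"] = False
            continue
        core = "".join(rng.choice(_BASES, size=L))
        partner = core
        n_mut = int(round((1.0 - config.repeat_identity) * L))
        if n_mut:
            pos = rng.choice(L, size=n_mut, replace=False)
            partner = list(partner)
            for p in pos:
                cur = partner[p]
                partner[p] = rng.choice([b for b in "ACGT" if b != cur])
            partner = "".join(partner)
        if config.repeat_orientation == "inverted":
            partner = reverse_complement(partner)
        (us, ue), (ds, de) = row["up_g"], row["down_g"]
        u_off = int(rng.integers(300, 501))
        d_off = int(rng.integers(300, 501))
        u_start = us + u_off
        d_start = ds + d_off
        _write_seq(arr, u_start, core, "+")
        _write_seq(arr, d_start, partner, "+")
        repeat_feats.append(
            RepeatFeature(CHROM, u_start, u_start + L - 1, "+", "AluSyn")
        )
        repeat_feats.append(
            RepeatFeature(
                CHROM,
                d_start,
                d_start + L - 1,
                "-" if config.repeat_orientation == "inverted" else "+",
                "AluSyn",
            )
        )
        # decoy repeats: annotate random background in the second half of
        # each flanking intron, to make pair detection non-trivial
        for (is_, ie_) in (row["up_g"], row["down_g"]):
            if rng.random() < 0.3:
                mid = is_ + (ie_ - is_) // 2 + 100
                if mid + 40 < ie_ - 300:
                    repeat_feats.append(
                        RepeatFeature(CHROM, mid, mid + 39, "+", "AluY")
                    )
        row["has_rcm"] = True
        repeat_rows.append(
            {
                "circ_id": circ_key(CHROM, row["start"], row["end"]),
                "up_start": u_start,
                "up_end": u_start + L - 1,
                "down_start": d_start,
                "down_end": d_start + L - 1,
                "orientation": config.repeat_orientation,
                "length": L,
                "identity": config.repeat_identity,
            }
        )

    # --- motifs -------------------------------------------------------------
    motif_rows: list[dict] = []
    for row in circ_rows:
        row["has_motif"] = False
        if (
            row["is_extra"]
            or row["category"] != "exonic"
            or row["up_g"] is None
            or row["down_g"] is None
        ):
            continue
        if rng.random() >= config.frac_motif_loci:
            continue
        strand = row["gene"]["strand"]
        for pattern, region, copies in config.motif_plant:
            dna = rna_to_dna(pattern)
            m = len(dna)
            # genomic window of the transcript-orientation region
            if region == "downstream_250":
                win = (
                    (row["end"] + 1, row["end"] + 250)
                    if strand == "+"
                    else (row["start"] - 250, row["start"] - 1)
                )
            elif region == "upstream_250":
                win = (
                    (row["start"] - 250, row["start"] - 1)
                    if strand == "+"
                    else (row["end"] + 1, row["end"] + 250)
                )
            else:  # exon_body
                win = (row["start"], row["end"])
            for k in range(copies):
                off = 25 + k * (m + 5)
                if strand == "+":
                    g = win[0] + off if region != "upstream_250" else win[1] - off - m + 1
                    _write_seq(arr, g, dna, "+")
                else:
                    g = win[1] - off - m + 1 if region != "upstream_250" else win[0] + off
                    _write_seq(arr, g, dna, "-")
            motif_rows.append(
                {
                    "circ_id": circ_key(CHROM, row["start"], row["end"]),
                    "pattern": pattern,
                    "region": region,
                    "copies": copies,
                }
            )
            row["has_motif"] = True

    # --- annotation table ---------------------------------------------------
    gtf_rows = []
    for gene in genes:
        tx1 = f"{gene['gene_id']}.t1"
        for k, (s, e) in enumerate(gene["exons"], start=1):
            gtf_rows.append(
                {
                    "chrom": CHROM,
                    "source": "circsim",
                    "feature": "exon",
                    "start": s,
                    "end": e,
                    "strand": gene["strand"],
                    "gene_id": gene["gene_id"],
                    "transcript_id": tx1,
                    "exon_number": k,
                }
            )
        # alternative transcript (exon-skipping) for some non-circRNA genes
        if (
            not gene["is_circ"]
            and gene["n_ex"] >= 4
            and rng.random() < config.frac_alt_transcript
        ):
            skip = int(rng.integers(2, gene["n_ex"]))
            tx2 = f"{gene['gene_id']}.t2"
            num = 0
            for k, (s, e) in enumerate(gene["exons"], start=1):
                if k == skip:
                    continue
                num += 1
                gtf_rows.append(
                    {
                        "chrom": CHROM,
                        "source": "circsim",
                        "feature": "exon",
                        "start": s,
                        "end": e,
                        "strand": gene["strand"],
                        "gene_id": gene["gene_id"],
                        "transcript_id": tx2,
                        "exon_number": num,
                    }
                )
    gtf = pd.DataFrame(gtf_rows)

    # --- cassette exons from non-circRNA genes ------------------------------
    ce_rows = []
    noncirc = [g for g in genes if not g["is_circ"] and g["n_ex"] >= 3]
    n_ce = min(config.n_cassette_exons, len(noncirc))
    for p in np.sort(rng.choice(len(noncirc), size=n_ce, replace=False)):
        gene = noncirc[int(p)]
        k = int(rng.integers(2, gene["n_ex"]))
        s, e = gene["exons"][k - 1]
        ce_rows.append(
            {
                "gene_id": gene["gene_id"],
                "chrom": CHROM,
                "start": s,
                "end": e,
                "strand": gene["strand"],
                "psi": round(float(rng.uniform(5, 95)), 2),
                "direction": "down" if rng.random() < 0.5 else "up",
            }
        )
    cassette_exons = pd.DataFrame(ce_rows)

    # --- exon-chain labels for same-BSJ isoform pairs ------------------------
    chain_rows = []
    for row in circ_rows:
        i, j = row["exon_span"]
        if row["category"] == "exonic" and j - i >= 2:
            key = circ_key(CHROM, row["start"], row["end"])
            full = "-".join(f"e{k}" for k in range(i, j + 1))
            skipped = "-".join(f"e{k}" for k in range(i, j + 1) if k != i + 1)
            chain_rows.append({"circ_id": key, "chain": full})
            chain_rows.append({"circ_id": key, "chain": skipped})
    chains = pd.DataFrame(chain_rows, columns=["circ_id", "chain"])

    # --- fold changes --------------------------------------------------------
    # exact sign allocation: the planted up fraction IS frac_upregulated
    # (up to rounding), so direction summaries have a fixed known truth
    n_circ_total = len(circ_rows)
    n_diff = int(round(config.frac_differential * n_circ_total))
    diff_order = rng.permutation(n_circ_total)[:n_diff].tolist()
    diff_idx = set(diff_order)
    n_up = int(round(config.frac_upregulated * n_diff))
    lfc = np.zeros(n_circ_total)
    for rank, idx in enumerate(diff_order):
        sign = 1.0 if rank < n_up else -1.0
        lfc[idx] = sign * config.planted_log2fc

    circ_table = []
    for idx, row in enumerate(circ_rows):
        gene = row["gene"]
        up, down = row["up_g"], row["down_g"]
        if gene is not None and gene["strand"] == "-" and up is not None:
            up, down = down, up  # transcript orientation: upstream is genomic right
        circ_table.append(
            {
                "circ_id": circ_key(CHROM, row["start"], row["end"]),
                "chrom": CHROM,
                "start": row["start"],
                "end": row["end"],
                "strand": gene["strand"] if gene else ("+" if rng.random() < 0.5 else "-"),
                "gene_id": gene["gene_id"] if gene else "",
                "category": row["category"],
                "start_label": row["start_label"],
                "end_label": row["end_label"],
                "intron_index": row["intron_index"],
                "up_intron_start": up[0] if up else 0,
                "up_intron_end": up[1] if up else 0,
                "down_intron_start": down[0] if down else 0,
                "down_intron_end": down[1] if down else 0,
                "single_exon": row["exon_span"][0] == row["exon_span"][1] != 0
                and row["start_label"] == "annotated",
                "is_extra": row["is_extra"],
                "true_log2fc": lfc[idx],
                "is_differential": idx in diff_idx,
                "has_rcm": row.get("has_rcm", False),
                "has_motif": row.get("has_motif", False),
            }
        )
    circ_columns = [
        "circ_id", "chrom", "start", "end", "strand", "gene_id", "category",
        "start_label", "end_label", "intron_index", "up_intron_start",
        "up_intron_end", "down_intron_start", "down_intron_end", "single_exon",
        "is_extra", "true_log2fc", "is_differential", "has_rcm", "has_motif",
    ]
    circs = pd.DataFrame(circ_table, columns=circ_columns)
    if len(circs) and circs["circ_id"].duplicated().any():
        circs = circs.drop_duplicates("circ_id", keep="first").reset_index(drop=True)

    genome = {CHROM: "".join(arr)}
    manifest = TruthManifest(circs, pd.DataFrame(repeat_rows), pd.DataFrame(motif_rows), cassette_exons, chains)
    return genome, gtf, repeat_feats, manifest


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def simulate_counts(
    circs: pd.DataFrame, config: SimulationConfig, seed: int | None = None
):
    """Draw junction and linear counts for every planted circRNA.

    ``circs`` needs ``circ_id`` and ``true_log2fc`` columns.  Junction counts
    are negative binomial with mean ``base * 2^(log2FC * case)`` scaled by
    the sample's library size; linear counts are drawn independently, so the
    circular-linear correlation is ~0 by construction.  Dispersion -> 0
    degenerates to Poisson.
    """
    if config.library_size <= 0:
        raise ConfigError("library_size must be positive")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    n = config.n_samples_per_group
    if n < 1:
        raise ConfigError("need at least one sample per group")
    samples = [f"case_{i + 1:02d}" for i in range(n)] + [
        f"control_{i + 1:02d}" for i in range(n)
    ]
    group = np.array([1.0] * n + [0.0] * n)
    lib = np.round(rng.uniform(0.8, 1.2, size=2 * n) * config.library_size).astype(int)
    m = len(circs)
    base = config.base_mean_junction_reads * np.exp2(
        rng.normal(0.0, config.base_mean_log2_sigma, size=m)
    )
    lfc = circs["true_log2fc"].to_numpy(dtype=float)
    mu = (
        base[:, None]
        * np.exp2(lfc[:, None] * group[None, :])
        * (lib[None, :] / config.library_size)
    )
    counts = _nb_draw(rng, mu, config.nb_dispersion)
    lin_base = config.linear_base_mean * np.exp2(
        rng.normal(0.0, config.base_mean_log2_sigma, size=m)
    )
    mu_lin = lin_base[:, None] * (lib[None, :] / config.library_size)
    linear = _nb_draw(rng, mu_lin, config.nb_dispersion)
    idx = pd.Index(circs["circ_id"], name="circ_id")
    counts = pd.DataFrame(counts, index=idx, columns=samples)
    linear = pd.DataFrame(linear, index=idx, columns=samples)
    sheet = pd.DataFrame(
        {
            "sample_id": samples,
            "group": ["case"] * n + ["control"] * n,
            "mappable_reads": lib,
            "tissue": "synthetic",
        }
    )
    return counts, linear, sheet


def _nb_draw(rng, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion < 1e-12:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    p = 1.0 / (1.0 + dispersion * mu)
    return rng.negative_binomial(r, p)


# ---------------------------------------------------------------------------
# emission
# ---------------------------------------------------------------------------

def _gtf_lines(gtf: pd.DataFrame) -> str:
    lines = []
    for row in gtf.itertuples(index=False):
        attrs = (
            f'gene_id "{row.gene_id}"; transcript_id "{row.transcript_id}"; '
            f'exon_number "{row.exon_number}";'
        )
        lines.append(
            f"{row.chrom}\t{row.source}\t{row.feature}\t{row.start}\t{row.end}"
            f"\t.\t{row.strand}\t.\t{attrs}"
        )
    return "\n".join(lines) + "\n"


_TYPE_BY_CATEGORY = {
    "exonic": "exon",
    "intronic": "intron",
    "exonic+intronic": "exon",
    "intergenic": "intergenic_region",
}


def emit_dataset(dataset: SimulatedDataset, out_dir: str | os.PathLike) -> dict:
    """Write the full dataset to ``out_dir``; returns the path map."""
    out = Path(out_dir)
    (out / "samples").mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fa",
        "gtf": out / "annotation.gtf",
        "repeats": out / "repeats.bed",
        "sample_sheet": out / "sample_sheet.tsv",
        "truth_circs": out / "truth_circs.tsv",
        "truth_repeats": out / "truth_repeats.tsv",
        "truth_motifs": out / "truth_motifs.tsv",
        "cassette_exons": out / "cassette_exons.tsv",
        "chains": out / "chains.tsv",
    }
    write_fasta(dataset.genome, paths["genome"])
    with open(paths["gtf"], "w") as fh:
        fh.write(_gtf_lines(dataset.gtf))
    write_bed(dataset.repeats, paths["repeats"])
    write_tsv(dataset.sample_sheet, paths["sample_sheet"], sort=False)
    m = dataset.manifest
    write_tsv(m.circs, paths["truth_circs"], sort=False)
    write_tsv(m.repeats, paths["truth_repeats"], sort=False)
    write_tsv(m.motifs, paths["truth_motifs"], sort=False)
    write_tsv(m.cassette_exons, paths["cassette_exons"], sort=False)
    write_tsv(m.chains, paths["chains"], sort=False)

    meta = m.circs.set_index("circ_id")
    sample_paths = {}
    for sid in dataset.counts.columns:
        records = []
        for cid, jr in dataset.counts[sid].items():
            if jr < 1:
                continue
            row = meta.loc[cid]
            records.append(
                CircRecord(
                    circ_id=cid,
                    chrom=row["chrom"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row["strand"],
                    junction_reads=int(jr),
                    non_junction_reads=int(dataset.linear.at[cid, sid]),
                    reported_type=_TYPE_BY_CATEGORY[row["category"]],
                    gene_id=row["gene_id"] if isinstance(row["gene_id"], str) else "",
                    sample_id=sid,
                )
            )
        p = out / "samples" / f"{sid}.ciri.tsv"
        write_ciri_table(records, p)
        sample_paths[sid] = p
    paths["samples"] = sample_paths
    dataset.paths = paths
    return paths


def generate_dataset(
    config: SimulationConfig | None = None,
    out_dir: str | os.PathLike | None = None,
    seed: int | None = None,
) -> SimulatedDataset:
    """One-call convenience: build loci, simulate counts, optionally emit."""
    if config is None:
        config = SimulationConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    genome, gtf, repeats, manifest = build_locus_set(config)
    counts, linear, sheet = simulate_counts(manifest.circs, config)
    ds = SimulatedDataset(config, genome, gtf, repeats, manifest, counts, linear, sheet)
    if out_dir is not None:
        emit_dataset(ds, out_dir)
    return ds
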