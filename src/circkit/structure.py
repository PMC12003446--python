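"""Structural classification of circRNAs and gene-level summaries.

Each BSJ end is assigned a context against the host gene's transcripts —
``exon_boundary`` (exact match to an annotated exon start/end, with optional
slop), ``inside_exon``, ``inside_intron`` or ``outside_gene``, in that order
of precedence — and the pair of contexts determines one of six structural
categories: exonic, intronic, exonic+intronic, exonic+intergenic,
intronic+intergenic, intergenic.

Length is the genomic span (end - start + 1) by default, binned into the
classes <200, 200-1000, 1000-5000, >5000 nt (lower edge inclusive); the
spliced length is reported only when exon-chain evidence is supplied.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CircRecord, GeneModel

DEFAULT_LENGTH_BINS = (200, 1000, 5000)

CATEGORIES = (
    "exonic",
    "intronic",
    "exonic+intronic",
    "exonic+intergenic",
    "intronic+intergenic",
    "intergenic",
)


@dataclass
class StructureCall:
    circ_id: str
    gene_id: str
    category: str
    genomic_span: int
    length_class: str
    end5_context: str
    end3_context: str
    strand_mismatch: bool = False
    ambiguous: bool = False
    spliced_length: int | None = None


def _end_context(
    pos: int, gene: GeneModel, slop: int = 0
) -> tuple[str, tuple[int, int] | None]:
    """Context of one genomic position against one gene.

    Returns (context, containing_intron_or_None); the intron is only
    reported for ``inside_intron`` so the caller can test the both-ends-in-
    one-intron rule.
    """
    for b in gene.exon_starts() | gene.exon_ends():
        if abs(pos - b) <= slop:
            return "exon_boundary", None
    for s, e in gene.all_exons():
        if s <= pos <= e:
            return "inside_exon", None
    if gene.contains(pos):
        # locate the containing intron of any transcript
        for tx in sorted(gene.transcripts):
            for iv in gene.introns(tx):
                if iv[0] <= pos <= iv[1]:
                    return "inside_intron", iv
        return "inside_intron", None
    return "outside_gene", None


_EXONIC = {"exon_boundary", "inside_exon"}


def _category(c5: str, c3: str, same_intron: bool) -> str:
    if c5 in _EXONIC and c3 in _EXONIC:
        return "exonic"
    if c5 == "inside_intron" and c3 == "inside_intron":
        return "intronic" if same_intron else "exonic+intronic"
    if c5 == "outside_gene" and c3 == "outside_gene":
        return "intergenic"
    if "outside_gene" in (c5, c3):
        inner = c3 if c5 == "outside_gene" else c5
        return (
            "intronic+intergenic"
            if inner == "inside_intron"
            else "exonic+intergenic"
        )
    return "exonic+intronic"


def classify_structure(
    circ: CircRecord,
    models: Mapping[str, GeneModel],
    length_bins: Sequence[int] = DEFAULT_LENGTH_BINS,
    boundary_slop: int = 0,
) -> StructureCall:
    """Assign the structural category and length class of one circRNA.

    Classification runs against the gene named in the record; when that is
    absent, the gene whose span covers most of the circRNA is used and the
    call flagged ambiguous.  A circRNA overlapping no gene at all is
    intergenic.
    """
    gene = models.get(circ.gene_id)
    ambiguous = False
    if gene is None:
        overlapping = [
            g
            for g in models.values()
            if g.chrom in ("", circ.chrom)
            and g.span[0] <= circ.end
            and g.span[1] >= circ.start
        ]
        if overlapping:
            gene = max(
                overlapping,
                key=lambda g: min(g.span[1], circ.end) - max(g.span[0], circ.start),
            )
            ambiguous = True
    if gene is None:
        c5 = c3 = "outside_gene"
        category = "intergenic"
        gene_id, mismatch = "", False
    else:
        c5, intron5 = _end_context(circ.start, gene, boundary_slop)
        c3, intron3 = _end_context(circ.end, gene, boundary_slop)
        same_intron = (
            intron5 is not None and intron5 == intron3
        ) or (
            c5 == c3 == "inside_intron" and intron5 is None and intron3 is None
        )
        category = _category(c5, c3, same_intron)
        gene_id = gene.gene_id
        mismatch = gene.strand != circ.strand
    span = circ.genomic_span
    return StructureCall(
        circ_id=circ.key,
        gene_id=gene_id,
        category=category,
        genomic_span=span,
        length_class=length_class(span, length_bins),
        end5_context=c5,
        end3_context=c3,
        strand_mismatch=mismatch,
        ambiguous=ambiguous,
    )


def length_class(span: int, bins: Sequence[int] = DEFAULT_LENGTH_BINS) -> str:
    """Bin a genomic span; lower edges are inclusive (span 200 -> 200-1000)."""
    edges = list(bins)
    if span < edges[0]:
        return f"<{edges[0]}"
    for lo, hi in zip(edges, edges[1:]):
        if lo <= span < hi:
            return f"{lo}-{hi}"
    return f">{edges[-1]}"


def category_table(calls: Iterable[StructureCall]) -> pd.DataFrame:
    """Counts and percentages per category and per length class."""
    df = pd.DataFrame(
        [(c.category, c.length_class) for c in calls],
        columns=["category", "length_class"],
    )
    out = (
        df.groupby(["category", "length_class"]).size().rename("n").reset_index()
    )
    out["pct"] = 100.0 * out["n"] / out["n"].sum()
    return out.sort_values(["category", "length_class"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# gene summaries
# ---------------------------------------------------------------------------

@dataclass
class GeneSummaryResult:
    table: pd.DataFrame
    pct_scg: float
    pct_mcg: float
    r2_vs_length: float | None
    r2_vs_expression: float | None


def summarize_genes(
    calls: Iterable[StructureCall],
    models: Mapping[str, GeneModel] | None = None,
    linear_rpm: Mapping[str, float] | pd.Series | None = None,
    top_mcg_threshold: int = 10,
) -> GeneSummaryResult:
    """Per-gene distinct circRNA counts, SCG/MCG split and correlations.

    A single-circRNA gene (SCG) hosts exactly one distinct BSJ, a
    multi-circRNA gene (MCG) two or more; "top" MCGs host more than
    ``top_mcg_threshold``.  Pearson R² of circRNA count against gene length
    and against mean linear expression is reported (0 when either side is
    constant; None when not computable).  Counts are invariant to row order
    and duplicate records.
    """
    per_gene: dict[str, set[str]] = {}
    for c in calls:
        if not c.gene_id:
            continue
        per_gene.setdefault(c.gene_id, set()).add(c.circ_id)
    rows = []
    for gene_id in sorted(per_gene):
        n = len(per_gene[gene_id])
        length = np.nan
        if models is not None and gene_id in models:
            length = models[gene_id].length
        expr = np.nan
        if linear_rpm is not None and gene_id in linear_rpm:
            expr = float(linear_rpm[gene_id])
        rows.append(
            {
                "gene_id": gene_id,
                "n_distinct_circ": n,
                "class": "SCG" if n == 1 else "MCG",
                "is_top_mcg": n > top_mcg_threshold,
                "gene_length": length,
                "gene_expression": expr,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "n_distinct_circ",
            "class",
            "is_top_mcg",
            "gene_length",
            "gene_expression",
        ],
    )
    n_genes = len(table)
    pct_scg = 100.0 * (table["class"] == "SCG").mean() if n_genes else float("nan")
    pct_mcg = 100.0 * (table["class"] == "MCG").mean() if n_genes else float("nan")

    def _r2(x: pd.Series, y: pd.Series) -> float | None:
        mask = x.notna() & y.notna()
        if mask.sum() < 3:
            return None
        xv, yv = x[mask].to_numpy(float), y[mask].to_numpy(float)
        if np.ptp(xv) == 0 or np.ptp(yv) == 0:
            return 0.0
        return float(stats.pearsonr(xv, yv).statistic ** 2)

    return GeneSummaryResult(
        table=table,
        pct_scg=pct_scg,
        pct_mcg=pct_mcg,
        r2_vs_length=_r2(table["n_distinct_circ"], table["gene_length"]),
        r2_vs_expression=_r2(table["n_distinct_circ"], table["gene_expression"]),
    )


# ---------------------------------------------------------------------------
# isoform grouping
# ---------------------------------------------------------------------------

@dataclass
class IsoformGroup:
    kind: str  # same_bsj | shared_donor | shared_acceptor
    members: tuple[str, ...]
    chains: tuple[str, ...] = ()


def group_isoforms(
    calls: pd.DataFrame, chains: pd.DataFrame | None = None
) -> list[IsoformGroup]:
    """Group circRNAs into isoform families.

    ``calls`` needs circ_id, chrom, start, end, strand, gene_id columns.
    ``same_bsj`` groups require exon-chain evidence: one BSJ with >= 2
    distinct chain labels.  ``shared_donor``/``shared_acceptor`` groups are
    distinct BSJs of one gene sharing exactly the donor-side (acceptor-side)
    end; the donor end is ``end`` on plus-strand genes and ``start`` on
    minus-strand genes.
    """
    groups: list[IsoformGroup] = []
    if chains is not None and len(chains):
        for cid, sub in chains.groupby("circ_id"):
            labels = tuple(sorted(set(sub["chain"])))
            if len(labels) >= 2:
                groups.append(IsoformGroup("same_bsj", (cid,), labels))
    df = calls.drop_duplicates("circ_id")
    df = df[df["gene_id"].astype(str) != ""]
    for gene_id, sub in df.groupby("gene_id"):
        strand = sub["strand"].iloc[0]
        donor_col, acceptor_col = ("end", "start") if strand == "+" else ("start", "end")
        for kind, col, other in (
            ("shared_donor", donor_col, acceptor_col),
            ("shared_acceptor", acceptor_col, donor_col),
        ):
            for _, g in sub.groupby(col):
                if g[other].nunique() >= 2:
                    groups.append(
                        IsoformGroup(kind, tuple(sorted(g["circ_id"])))
                    )
    groups.sort(key=lambda g: (g.kind, g.members))
    return groups


# ---------------------------------------------------------------------------
# cross-dataset overlap
# ---------------------------------------------------------------------------

def intersect_datasets(named_sets: Mapping[str, set]) -> pd.DataFrame:
    """Venn-style region counts for 2-3 named circRNA key sets.

    One row per non-empty membership pattern plus a per-set shared fraction
    (fraction of the set's keys found in at least one other set).
    """
    names = list(named_sets)
    if not 2 <= len(names) <= 3:
        raise ValueError("need 2 or 3 named sets")
    rows = []
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(named_sets[n] for n in combo))
            outside = set.union(
                *(named_sets[n] for n in names if n not in combo), set()
            )
            rows.append(
                {
                    "region": "&".join(combo),
                    "n": len(inside - outside),
                }
            )
    table = pd.DataFrame(rows)
    for n in names:
        others = set.union(*(named_sets[m] for m in names if m != n))
        size = len(named_sets[n])
        table.loc[table["region"] == n, "set_size"] = size
        table.loc[table["region"] == n, "frac_shared"] = (
            len(named_sets[n] & others) / size if size else float("nan")
        )
    return table
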