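"""Readers and writers for every external file the pipeline touches.

All coordinates are held 1-based inclusive internally (the convention of both
CIRI2 tables and GTF).  BED input is converted on read; no other conversion
happens anywhere else in the package.  Chromosome names are matched as exact
strings across inputs.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

# CIRI2 output dialect, columns in order.  Only the named subset is consumed;
# SM_MS_SMS, junction_reads_ratio and junction_reads_ID are carried opaquely.
CIRI_COLUMNS = [
    "circRNA_ID",
    "chr",
    "circRNA_start",
    "circRNA_end",
    "#junction_reads",
    "SM_MS_SMS",
    "#non_junction_reads",
    "junction_reads_ratio",
    "circRNA_type",
    "gene_id",
    "strand",
    "junction_reads_ID",
]

_REQUIRED_CIRI = {
    "circRNA_ID",
    "chr",
    "circRNA_start",
    "circRNA_end",
    "#junction_reads",
    "#non_junction_reads",
    "circRNA_type",
    "gene_id",
    "strand",
}

VALID_TYPES = {"exon", "intron", "intergenic_region", "unknown"}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N kept)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """An input file violates its declared dialect."""


def circ_key(chrom: str, start: int, end: int) -> str:
    """Canonical circRNA identifier ``chrom:start|end``."""
    return f"{chrom}:{start}|{end}"


@dataclass(frozen=True)
class CircRecord:
    """One back-splice junction call from one sample.

    ``start``/``end`` are 1-based inclusive genomic positions of the BSJ
    acceptor-side and donor-side boundaries (``end >= start``).
    """

    circ_id: str
    chrom: str
    start: int
    end: int
    strand: str
    junction_reads: int
    non_junction_reads: int
    reported_type: str
    gene_id: str
    sample_id: str
    intergenic_flag: bool = False

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"{self.circ_id}: end < start")
        if self.junction_reads < 0 or self.non_junction_reads < 0:
            raise ValueError(f"{self.circ_id}: negative read count")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.circ_id}: strand {self.strand!r}")

    @property
    def key(self) -> str:
        return circ_key(self.chrom, self.start, self.end)

    @property
    def genomic_span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class RepeatFeature:
    """A repeat-annotation interval (1-based inclusive after BED conversion)."""

    chrom: str
    start: int
    end: int
    strand: str
    family: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"repeat {self.family}: end < start")


class GeneModel:
    """Transcripts of one gene, with introns derived as inter-exon gaps.

    Exons are stored per transcript as sorted, non-overlapping 1-based
    inclusive ``(start, end)`` tuples in genomic order.  Transcript-orientation
    accessors reverse the order for minus-strand genes.
    """

    def __init__(self, gene_id: str, strand: str, chrom: str = "") -> None:
        self.gene_id = gene_id
        self.strand = strand
        self.chrom = chrom
        self.transcripts: dict[str, list[tuple[int, int]]] = {}

    def add_exon(self, transcript_id: str, start: int, end: int) -> None:
        self.transcripts.setdefault(transcript_id, []).append((start, end))

    def finalize(self) -> None:
        """Sort exons and validate non-overlap within each transcript."""
        for tx, exons in self.transcripts.items():
            exons.sort()
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                if s2 <= e1:
                    raise FormatError(
                        f"gene {self.gene_id} transcript {tx}: overlapping "
                        f"exons ({s1},{e1}) and ({s2},{e2})"
                    )

    # -- genomic-order accessors ------------------------------------------
    def exons(self, transcript_id: str) -> list[tuple[int, int]]:
        return list(self.transcripts[transcript_id])

    def introns(self, transcript_id: str) -> list[tuple[int, int]]:
        """Inter-exon gaps in genomic order; every intron has length >= 1."""
        exons = self.transcripts[transcript_id]
        return [
            (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(exons, exons[1:])
        ]

    # -- transcript-orientation accessors ---------------------------------
    def exons_tx_order(self, transcript_id: str) -> list[tuple[int, int]]:
        exons = self.exons(transcript_id)
        return exons if self.strand == "+" else exons[::-1]

    def introns_tx_order(self, transcript_id: str) -> list[tuple[int, int]]:
        introns = self.introns(transcript_id)
        return introns if self.strand == "+" else introns[::-1]

    # -- gene-level summaries ----------------------------------------------
    @property
    def span(self) -> tuple[int, int]:
        starts = [s for ex in self.transcripts.values() for s, _ in ex]
        ends = [e for ex in self.transcripts.values() for _, e in ex]
        return min(starts), max(ends)

    @property
    def length(self) -> int:
        s, e = self.span
        return e - s + 1

    def exon_starts(self) -> set[int]:
        return {s for ex in self.transcripts.values() for s, _ in ex}

    def exon_ends(self) -> set[int]:
        return {e for ex in self.transcripts.values() for _, e in ex}

    def all_exons(self) -> set[tuple[int, int]]:
        return {iv for ex in self.transcripts.values() for iv in ex}

    def contains(self, pos: int) -> bool:
        s, e = self.span
        return s <= pos <= e


class GenomeAccessor:
    """Uppercase sequence access over a FASTA file, 1-based inclusive.

    Minus-strand requests return the reverse complement.
    """

    def __init__(self, path: str | os.PathLike) -> None:
        self._fasta = Fasta(str(path), sequence_always_upper=True)

    @property
    def chroms(self) -> list[str]:
        return list(self._fasta.keys())

    def length(self, chrom: str) -> int:
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        if chrom not in self._fasta:
            raise KeyError(f"unknown chromosome {chrom!r}")
        n = len(self._fasta[chrom])
        if start < 1 or end > n or end < start:
            raise IndexError(
                f"request {chrom}:{start}-{end} outside contig of length {n}"
            )
        seq = str(self._fasta[chrom][start - 1 : end])
        return reverse_complement(seq) if strand == "-" else seq

    def base_frequencies(self) -> dict[str, float]:
        """Genome-wide A/C/G/T frequencies (N excluded)."""
        counts = {b: 0 for b in "ACGT"}
        for chrom in self._fasta.keys():
            seq = str(self._fasta[chrom][:])
            for b in "ACGT":
                counts[b] += seq.count(b)
        total = sum(counts.values())
        return {b: c / total for b, c in counts.items()}


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_ciri_table(path: str | os.PathLike, sample_id: str) -> list[CircRecord]:
    """Parse one CIRI2-dialect TSV into :class:`CircRecord` objects.

    Intergenic calls are retained but flagged (they are excluded from
    structural/locus analyses downstream).  Duplicate rows for the same
    (chrom, start, end, strand) within one sample have their junction and
    non-junction reads summed, with a logged warning.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = _REQUIRED_CIRI - set(header)
        if missing:
            raise FormatError(
                f"{path}: missing CIRI2 column(s): {', '.join(sorted(missing))}"
            )
        idx = {name: header.index(name) for name in header}
        records: dict[tuple[str, int, int, str], CircRecord] = {}
        dupes = 0
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < len(header):
                raise FormatError(f"{path}:{lineno}: short row")

            def col(name: str) -> str:
                return fields[idx[name]]

            try:
                start = int(col("circRNA_start"))
                end = int(col("circRNA_end"))
                jr = int(col("#junction_reads"))
                njr = int(col("#non_junction_reads"))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field: {exc}")
            strand = col("strand")
            if strand not in {"+", "-"}:
                raise FormatError(
                    f"{path}:{lineno}: strand must be + or -, got {strand!r}"
                )
            rtype = col("circRNA_type")
            if rtype not in VALID_TYPES:
                rtype = "unknown"
            rec = CircRecord(
                circ_id=col("circRNA_ID"),
                chrom=col("chr"),
                start=start,
                end=end,
                strand=strand,
                junction_reads=jr,
                non_junction_reads=njr,
                reported_type=rtype,
                gene_id=col("gene_id").strip().strip(","),
                sample_id=sample_id,
                intergenic_flag=(rtype == "intergenic_region"),
            )
            k = (rec.chrom, rec.start, rec.end, rec.strand)
            if k in records:
                prev = records[k]
                dupes += 1
                records[k] = CircRecord(
                    circ_id=prev.circ_id,
                    chrom=prev.chrom,
                    start=prev.start,
                    end=prev.end,
                    strand=prev.strand,
                    junction_reads=prev.junction_reads + rec.junction_reads,
                    non_junction_reads=prev.non_junction_reads
                    + rec.non_junction_reads,
                    reported_type=prev.reported_type,
                    gene_id=prev.gene_id,
                    sample_id=sample_id,
                    intergenic_flag=prev.intergenic_flag,
                )
            else:
                records[k] = rec
        if dupes:
            logger.warning(
                "%s: %d duplicate circRNA row(s) merged by summing reads",
                path,
                dupes,
            )
    return list(records.values())


def read_gene_models(path: str | os.PathLike) -> dict[str, GeneModel]:
    """Load exon features from an Ensembl-dialect GTF into gene models.

    Only ``exon`` features are consumed.  Exons missing a ``transcript_id``
    are skipped with a logged warning; overlapping exons within a transcript
    raise :class:`FormatError`.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    models: dict[str, GeneModel] = {}
    skipped = 0
    for feat in db.features_of_type("exon"):
        gene_ids = feat.attributes.get("gene_id")
        tx_ids = feat.attributes.get("transcript_id")
        if not tx_ids:
            skipped += 1
            continue
        gene_id = gene_ids[0] if gene_ids else tx_ids[0]
        model = models.get(gene_id)
        if model is None:
            model = GeneModel(gene_id, feat.strand, chrom=feat.seqid)
            models[gene_id] = model
        model.add_exon(tx_ids[0], feat.start, feat.end)
    if skipped:
        logger.warning("%s: skipped %d exon(s) without transcript_id", path, skipped)
    for model in models.values():
        model.finalize()
    return models


def read_repeat_annotation(path: str | os.PathLike) -> list[RepeatFeature]:
    """Parse a BED6 repeat track; coordinates become 1-based inclusive."""
    feats: list[RepeatFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected BED6")
            chrom, start0, end0, name, _score, strand = fields[:6]
            start0, end0 = int(start0), int(end0)
            if end0 <= start0:
                raise FormatError(
                    f"{path}:{lineno}: end <= start in BED record"
                )
            feats.append(
                RepeatFeature(
                    chrom=chrom,
                    start=start0 + 1,
                    end=end0,
                    strand=strand,
                    family=name,
                )
            )
    return feats


def read_genome(path: str | os.PathLike) -> GenomeAccessor:
    """Open a FASTA file for strand-aware, 1-based inclusive access."""
    return GenomeAccessor(path)


def read_sample_sheet(path: str | os.PathLike) -> pd.DataFrame:
    """Sample sheet TSV: sample_id, group (case/control), mappable_reads, tissue."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "tissue": str})
    required = {"sample_id", "group", "mappable_reads"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    if (df["mappable_reads"] <= 0).any():
        raise FormatError(f"{path}: mappable_reads must be positive")
    bad = set(df["group"]) - {"case", "control"}
    if bad:
        raise FormatError(f"{path}: unknown group label(s) {sorted(bad)}")
    if "tissue" not in df.columns:
        df["tissue"] = ""
    return df


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_SORT_PRIORITY = ["chrom", "start", "end", "circ_id", "gene_id", "sample_id"]


def write_tsv(df: pd.DataFrame, path: str | os.PathLike, sort: bool = True) -> None:
    """Write a TSV with deterministic row and column order.

    Rows are sorted by whatever subset of (chrom, start, end, circ_id,
    gene_id, sample_id) the frame carries, so repeated runs are
    byte-identical.
    """
    out = df.copy()
    if sort and len(out):
        keys = [c for c in _SORT_PRIORITY if c in out.columns]
        if keys:
            out = out.sort_values(keys, kind="mergesort")
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_result_tables(
    results: Mapping[str, pd.DataFrame], out_dir: str | os.PathLike
) -> dict[str, Path]:
    """Write each named DataFrame as ``<name>.tsv`` under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name in sorted(results):
        p = out_dir / f"{name}.tsv"
        write_tsv(results[name], p)
        paths[name] = p
    return paths


def write_ciri_table(records: Sequence[CircRecord], path: str | os.PathLike) -> None:
    """Emit records in the CIRI2 output dialect (opaque columns filled in)."""
    rows = []
    for r in sorted(records, key=lambda r: (r.chrom, r.start, r.end)):
        denom = 2 * r.junction_reads + r.non_junction_reads
        ratio = (2 * r.junction_reads / denom) if denom else 0.0
        rows.append(
            {
                "circRNA_ID": r.circ_id,
                "chr": r.chrom,
                "circRNA_start": r.start,
                "circRNA_end": r.end,
                "#junction_reads": r.junction_reads,
                "SM_MS_SMS": "0_0_0",
                "#non_junction_reads": r.non_junction_reads,
                "junction_reads_ratio": f"{ratio:.3f}",
                "circRNA_type": r.reported_type,
                "gene_id": r.gene_id,
                "strand": r.strand,
                "junction_reads_ID": ".",
            }
        )
    pd.DataFrame(rows, columns=CIRI_COLUMNS).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_bed(feats: Iterable[RepeatFeature], path: str | os.PathLike) -> None:
    """Write repeats as BED6 (internal 1-based inclusive -> 0-based half-open)."""
    with open(path, "w") as fh:
        for f in sorted(feats, key=lambda f: (f.chrom, f.start, f.end)):
            fh.write(
                f"{f.chrom}\t{f.start - 1}\t{f.end}\t{f.family}\t0\t{f.strand}\n"
            )
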