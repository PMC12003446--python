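"""Shared fixtures: hand-built toy loci and a session-wide synthetic dataset."""

from __future__ import annotations

from pathlib import Path

import pytest

from circkit import io_formats
from circkit.synthetic_data import SimulationConfig, generate_dataset

# Toy gene: three exons [1,100], [201,300], [401,500] -> introns [101,200],
# [301,400].  One plus-strand and one mirrored minus-strand copy.
TOY_GTF = """\
chrT\ttest\texon\t1\t100\t.\t+\t.\tgene_id "GPLUS"; transcript_id "GPLUS.t1";
chrT\ttest\texon\t201\t300\t.\t+\t.\tgene_id "GPLUS"; transcript_id "GPLUS.t1";
chrT\ttest\texon\t401\t500\t.\t+\t.\tgene_id "GPLUS"; transcript_id "GPLUS.t1";
chrT\ttest\texon\t601\t700\t.\t-\t.\tgene_id "GMINUS"; transcript_id "GMINUS.t1";
chrT\ttest\texon\t801\t900\t.\t-\t.\tgene_id "GMINUS"; transcript_id "GMINUS.t1";
chrT\ttest\texon\t1001\t1100\t.\t-\t.\tgene_id "GMINUS"; transcript_id "GMINUS.t1";
"""


@pytest.fixture(scope="session")
def toy_models(tmp_path_factory):
    p = tmp_path_factory.mktemp("toy") / "toy.gtf"
    p.write_text(TOY_GTF)
    return io_formats.read_gene_models(p)


def make_circ(
    start,
    end,
    strand="+",
    gene_id="GPLUS",
    chrom="chrT",
    junction_reads=5,
    sample_id="s1",
    reported_type="exon",
):
    return io_formats.CircRecord(
        circ_id=f"{chrom}:{start}|{end}",
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        junction_reads=junction_reads,
        non_junction_reads=0,
        reported_type=reported_type,
        gene_id=gene_id,
        sample_id=sample_id,
    )


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """The default-configuration synthetic dataset, emitted once per session."""
    out = tmp_path_factory.mktemp("dataset")
    return generate_dataset(SimulationConfig(seed=1), out)


@pytest.fixture(scope="session")
def dataset_models(default_dataset):
    return io_formats.read_gene_models(default_dataset.paths["gtf"])


@pytest.fixture(scope="session")
def dataset_genome(default_dataset):
    return io_formats.read_genome(default_dataset.paths["genome"])


@pytest.fixture(scope="session")
def small_config():
    """A fast, small configuration for end-to-end smoke tests."""
    return SimulationConfig(
        seed=3,
        n_genes=30,
        n_samples_per_group=3,
        intron_length_flanking=(2000, 4000),
    )
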