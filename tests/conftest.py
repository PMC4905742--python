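import numpy as np
import pytest

from ppa_scout.coverage import BlockedRead, write_bed12
from ppa_scout.genemodel import GenomicInterval, split_intron
from ppa_scout.simdata import demo_gene_model


@pytest.fixture
def model():
    return demo_gene_model()


@pytest.fixture
def split(model):
    return split_intron(model)


@pytest.fixture
def intron(model):
    return model.target_intron


def iv(start, end, chrom="chr1", strand="+"):
    return GenomicInterval(chrom, start, end, strand)


def single_block_read(read_id, start, end, chrom="chr1", strand="+"):
    return BlockedRead(read_id, (iv(start, end, chrom, strand),))


def random_blocked_reads(rng, n, lo, hi, max_blocks=3, chrom="chr1"):
    """Random non-overlapping sorted blocks inside [lo, hi)."""
    reads = []
    for k in range(n):
        n_blocks = int(rng.integers(1, max_blocks + 1))
        cuts = np.sort(rng.choice(np.arange(lo, hi), size=2 * n_blocks, replace=False))
        blocks = tuple(
            iv(int(cuts[2 * i]), int(cuts[2 * i + 1]), chrom)
            for i in range(n_blocks)
        )
        reads.append(BlockedRead(f"r{k}", blocks))
    return reads


@pytest.fixture
def model_files(tmp_path, model):
    """Demo model written as BED12 annotation + TOML config (for CLI and
    loader tests)."""
    bed = tmp_path / "model.bed12"
    isoform_reads = [
        BlockedRead(name, model.exons_genomic(name))
        for name in model.isoforms
    ]
    write_bed12(isoform_reads, bed)
    toml = tmp_path / "model.toml"
    toml.write_text(
        'annotation = "model.bed12"\n'
        'gene_id = "DEMO1"\n'
        'strand = "+"\n'
        "pas_position = 2194\n"
        "cleavage_offset = 0\n"
        "\n"
        "[target_intron]\n"
        'chrom = "chr1"\n'
        "start = 1200\n"
        "end = 5200\n"
        "\n"
        "[unique_regions]\n"
        "pPA = [[1200, 2200]]\n"
        "FL_alpha = [[6000, 7000]]\n"
        "FL_beta = [[7500, 8200]]\n"
    )
    return {"toml": toml, "bed": bed}
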