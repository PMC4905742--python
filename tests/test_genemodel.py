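import numpy as np
import pytest

from ppa_scout.examples import (
    JUNCTION_EXON_TAIL,
    JUNCTION_FRAME_OFFSET,
    JUNCTION_INTRON_SEQ,
)
from ppa_scout.genemodel import (
    GeneModel,
    GenomicInterval,
    ModelParseError,
    ModelValidationError,
    find_premature_stop,
    load_gene_model,
    split_intron,
)

from conftest import iv


# ---------------------------------------------------------------------------
# GenomicInterval / GeneModel invariants


def test_interval_requires_positive_length():
    with pytest.raises(ModelValidationError):
        GenomicInterval("chr1", 10, 10)
    with pytest.raises(ModelValidationError):
        GenomicInterval("chr1", 20, 10)


def test_interval_length_and_contains():
    region = iv(100, 200)
    assert region.length == 100
    assert region.contains(100) and region.contains(199)
    assert not region.contains(200)


def _toy_three_exon_model(pas_position=1994):
    # intron 2 = [1000, 5000); PAS mid-intron by default
    return GeneModel(
        gene_id="G",
        strand="+",
        isoforms={"FL": (iv(0, 500), iv(700, 1000), iv(5000, 5500))},
        target_intron=iv(1000, 5000),
        pas_position=pas_position,
    )


def test_toy_model_construction():
    model = _toy_three_exon_model()
    assert model.host_isoform() == "FL"
    assert model.target_intron == iv(1000, 5000)


def test_pas_inside_exon_rejected():
    with pytest.raises(ModelValidationError):
        _toy_three_exon_model(pas_position=800)


def test_overlapping_exons_rejected():
    with pytest.raises(ModelValidationError):
        GeneModel(
            gene_id="G",
            strand="+",
            isoforms={"FL": (iv(0, 500), iv(400, 1000), iv(5000, 5500))},
            target_intron=iv(1000, 5000),
            pas_position=1994,
        )


def test_intron_must_match_an_exon_gap():
    with pytest.raises(ModelValidationError):
        GeneModel(
            gene_id="G",
            strand="+",
            isoforms={"FL": (iv(0, 500), iv(700, 1000), iv(5000, 5500))},
            target_intron=iv(1100, 5000),
            pas_position=1994,
        )


def test_unique_regions_must_be_disjoint():
    with pytest.raises(ModelValidationError):
        GeneModel(
            gene_id="G",
            strand="+",
            isoforms={
                "FL": (iv(0, 500), iv(700, 1000), iv(5000, 5500)),
                "other": (iv(0, 500), iv(5000, 5500)),
            },
            target_intron=iv(1000, 5000),
            pas_position=1994,
            unique_regions={"FL": (iv(1000, 2000),), "other": (iv(1500, 2500),)},
        )


# ---------------------------------------------------------------------------
# split_intron


def test_split_plus_strand_default_offset():
    model = _toy_three_exon_model(pas_position=1994)
    split = split_intron(model)
    assert split.region_A == iv(1000, 2000)
    assert split.region_B == iv(2000, 5000)
    assert split.len_A == 1000 and split.len_B == 3000


def test_split_with_cleavage_offset():
    model = _toy_three_exon_model(pas_position=1994)
    split = split_intron(model, cleavage_offset=20)
    assert split.region_A.end == 2020
    assert split.len_A == 1020


def test_split_conserves_length_exactly():
    model = _toy_three_exon_model(pas_position=1994)
    for offset in (0, 1, 7, 500):
        split = split_intron(model, cleavage_offset=offset)
        assert split.len_A + split.len_B == model.target_intron.length


def test_split_boundary_outside_intron_errors():
    model = _toy_three_exon_model(pas_position=4993)
    with pytest.raises(ModelValidationError):
        split_intron(model, cleavage_offset=10)


def _minus_model(pas_position=4005):
    return GeneModel(
        gene_id="G",
        strand="-",
        isoforms={
            "FL": (
                iv(5000, 5200, strand="-"),
                iv(800, 1000, strand="-"),
            )
        },
        target_intron=iv(1000, 5000, strand="-"),
        pas_position=pas_position,
    )


def test_split_minus_strand_example():
    split = split_intron(_minus_model(pas_position=4005))
    assert split.region_A == iv(4000, 5000, strand="-")
    assert split.region_B == iv(1000, 4000, strand="-")
    assert split.len_A == 1000


@pytest.mark.parametrize("pas_minus", [4005, 4500, 1500, 2750])
@pytest.mark.parametrize("offset", [0, 13])
def test_split_minus_matches_mirrored_plus(pas_minus, offset):
    # mirror x -> C-1-x maps the minus-strand gene onto an equivalent
    # plus-strand gene; region A must map onto region A
    C = 6000
    minus = _minus_model(pas_position=pas_minus)

    def mirror_iv(region, strand):
        return iv(C - region.end, C - region.start, strand=strand)

    plus = GeneModel(
        gene_id="G",
        strand="+",
        isoforms={
            "FL": tuple(
                mirror_iv(e, "+") for e in minus.isoforms["FL"]
            )
        },
        target_intron=mirror_iv(minus.target_intron, "+"),
        pas_position=C - 1 - pas_minus,
    )
    s_minus = split_intron(minus, cleavage_offset=offset)
    s_plus = split_intron(plus, cleavage_offset=offset)
    assert mirror_iv(s_minus.region_A, "+") == s_plus.region_A
    assert mirror_iv(s_minus.region_B, "+") == s_plus.region_B
    assert s_minus.len_A == s_plus.len_A


# ---------------------------------------------------------------------------
# find_premature_stop


def test_bundled_junction_stop_offset_is_six():
    offset = find_premature_stop(
        JUNCTION_EXON_TAIL, JUNCTION_INTRON_SEQ, JUNCTION_FRAME_OFFSET
    )
    assert offset == 6


def test_stop_at_junction():
    assert find_premature_stop("ATG", "TAACCC", 0) == 0


def test_no_stop_returns_none():
    assert find_premature_stop("ATG", "AAACCCGGG", 0) is None


def test_non_acgt_rejected():
    with pytest.raises(ValueError):
        find_premature_stop("ATG", "ANA", 0)


def test_stop_spanning_junction_reports_zero():
    # frame_offset 2: exon contributes TG, intron starts with A -> TGA
    assert find_premature_stop("CCCTG", "ACCCCCC", 2) == 0


def _brute_force_stop_offset(exon_tail, intron_seq, frame_offset):
    """Codon-by-codon translation of the read-through frame."""
    combined = exon_tail + intron_seq
    first_codon = len(exon_tail) - frame_offset
    for c in range(first_codon, len(combined) - 2, 3):
        if combined[c : c + 3] in ("TAA", "TAG", "TGA"):
            return max(0, c - len(exon_tail))
    return None


def test_stop_offset_matches_bruteforce_translator():
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    for _ in range(1000):
        exon = "".join(rng.choice(bases, size=int(rng.integers(3, 30))))
        intron = "".join(rng.choice(bases, size=300))
        frame = int(rng.integers(0, 3))
        assert find_premature_stop(exon, intron, frame) == (
            _brute_force_stop_offset(exon, intron, frame)
        )


# ---------------------------------------------------------------------------
# load_gene_model


def test_load_from_bed12_and_toml(model_files, model):
    loaded = load_gene_model(model_files["bed"], model_files["toml"])
    assert loaded.gene_id == "DEMO1"
    assert loaded.isoforms == model.isoforms
    assert loaded.target_intron == model.target_intron
    assert loaded.unique_regions == model.unique_regions


def test_load_gff3_converts_coordinates(tmp_path):
    # GFF3 1-based inclusive 101..200 must become [100, 200)
    gff = tmp_path / "m.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\tsrc\texon\t101\t200\t.\t+\t.\tParent=FL\n"
        "chr1\tsrc\texon\t301\t400\t.\t+\t.\tParent=FL\n"
    )
    cfg = {
        "gene_id": "G",
        "strand": "+",
        "target_intron": {"chrom": "chr1", "start": 200, "end": 300},
        "pas_position": 240,
    }
    loaded = load_gene_model(gff, cfg)
    assert loaded.isoforms["FL"] == (iv(100, 200), iv(300, 400))


def test_load_gff3_malformed_names_line(tmp_path):
    gff = tmp_path / "bad.gff3"
    gff.write_text("chr1\tsrc\texon\t101\n")
    with pytest.raises(ModelParseError, match="bad.gff3:1"):
        load_gene_model(gff, {
            "gene_id": "G", "strand": "+",
            "target_intron": {"chrom": "chr1", "start": 200, "end": 300},
            "pas_position": 240,
        })


def test_load_rejects_pas_outside_intron(model_files):
    import tomllib

    cfg = tomllib.loads(model_files["toml"].read_text())
    cfg["pas_position"] = 6000
    with pytest.raises(ModelValidationError):
        load_gene_model(model_files["bed"], cfg)
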