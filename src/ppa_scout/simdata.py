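"""Seeded synthetic-cohort generator with ground truth.

Samples are mixtures of transcripts (full-length spliced isoforms, the
truncated isoform ending in region A, and an intron-retaining isoform).
Reads are drawn with uniform start positions in transcript coordinates
and projected back to genomic blocked reads, so spliced reads carry
splice gaps and intronic reads arise only from the truncated or
intron-retaining transcripts.  The full output stream is a pure function
of the configuration, including the seed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .coverage import ReadSet, write_bed12, write_bedgraph, compute_coverage
from .genemodel import GeneModel, GenomicInterval, split_intron

__all__ = [
    "SampleKind",
    "SampleSpec",
    "SimConfig",
    "Transcript",
    "CohortSim",
    "build_transcripts",
    "simulate_sample",
    "simulate_cohort",
    "write_cohort",
    "demo_gene_model",
    "default_cohort_config",
    "ppa_fraction_for_ratio",
]

PPA = "pPA"
IR = "IR"


class SampleKind(str, enum.Enum):
    NEGATIVE = "NEGATIVE"
    ISOLATED_NOISE = "ISOLATED_NOISE"
    INTRON_RETENTION = "INTRON_RETENTION"
    PPA = "PPA"
    PPA_GAPPED = "PPA_GAPPED"


@dataclass(frozen=True)
class SampleSpec:
    """Planted class of one simulated sample."""

    sample_id: str
    group: str
    kind: SampleKind
    retention_fraction: float = 0.0
    ppa_fraction: float = 0.0
    dropouts: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.kind is SampleKind.INTRON_RETENTION and not (
            0 < self.retention_fraction <= 1
        ):
            raise ValueError("retention_fraction must be in (0, 1]")
        if self.kind in (SampleKind.PPA, SampleKind.PPA_GAPPED) and not (
            0 < self.ppa_fraction <= 1
        ):
            raise ValueError("ppa_fraction must be in (0, 1]")
        if self.kind is SampleKind.PPA_GAPPED and not self.dropouts:
            raise ValueError("PPA_GAPPED requires at least one dropout interval")


@dataclass
class SimConfig:
    """Full cohort simulation configuration."""

    model: GeneModel
    samples: tuple[SampleSpec, ...]
    reads_per_sample: int = 120_000
    read_len: int = 50
    noise_reads: int = 3
    seed: int = 0
    fl_weights: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.read_len < 20:
            raise ValueError("read_len must be >= 20")
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be > 0")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in cohort")


# ---------------------------------------------------------------------------
# Transcripts and projection


@dataclass(frozen=True)
class Transcript:
    """A transcript as ordered genomic blocks (transcription order)."""

    name: str
    blocks: tuple[GenomicInterval, ...]
    strand: str

    @property
    def length(self) -> int:
        return sum(b.length for b in self.blocks)

    def cumlens(self) -> np.ndarray:
        return np.concatenate(
            [[0], np.cumsum([b.length for b in self.blocks])]
        )

    def project(self, t_start: int, t_end: int) -> tuple[tuple[int, int], ...]:
        """Map transcript interval ``[t_start, t_end)`` to genomic blocks
        in ascending genomic order."""
        if not 0 <= t_start < t_end <= self.length:
            raise ValueError(
                f"transcript interval [{t_start},{t_end}) outside "
                f"[0,{self.length})"
            )
        cum = self.cumlens()
        out: list[tuple[int, int]] = []
        for i, block in enumerate(self.blocks):
            lo = max(t_start, int(cum[i]))
            hi = min(t_end, int(cum[i + 1]))
            if hi <= lo:
                continue
            if self.strand == "+":
                g_lo = block.start + (lo - int(cum[i]))
                out.append((g_lo, g_lo + (hi - lo)))
            else:
                g_hi = block.end - (lo - int(cum[i]))
                out.append((g_hi - (hi - lo), g_hi))
        out.sort()
        # adjacent genomic blocks merge (e.g. exon flowing into region A)
        merged: list[tuple[int, int]] = []
        for s, e in out:
            if merged and merged[-1][1] == s:
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        return tuple(merged)


def _merge_adjacent(
    blocks: Sequence[GenomicInterval],
) -> tuple[GenomicInterval, ...]:
    ordered = sorted(blocks, key=lambda b: b.start)
    merged: list[GenomicInterval] = []
    for b in ordered:
        if merged and merged[-1].end == b.start:
            merged[-1] = GenomicInterval(b.chrom, merged[-1].start, b.end, b.strand)
        else:
            merged.append(b)
    return tuple(merged)


def build_transcripts(
    model: GeneModel, cleavage_offset: Optional[int] = None
) -> dict[str, Transcript]:
    """Transcript structures for every model isoform plus the truncated
    (``pPA``) and intron-retaining (``IR``) forms.

    The truncated transcript is the host isoform's exons upstream of the
    target intron followed by region A; the IR transcript is the host
    isoform with the full target intron retained.
    """
    strand = model.strand
    out: dict[str, Transcript] = {}
    for name, exons in model.isoforms.items():
        out[name] = Transcript(name, exons, strand)
    split = split_intron(model, cleavage_offset)
    host = model.host_isoform()
    assert host is not None
    upstream = model.upstream_exons(host)
    ppa_blocks = _merge_adjacent(list(upstream) + [split.region_A])
    if strand == "-":
        ppa_blocks = ppa_blocks[::-1]
    out.setdefault(PPA, Transcript(PPA, ppa_blocks, strand))
    ir_blocks = _merge_adjacent(
        list(model.isoforms[host]) + [model.target_intron]
    )
    if strand == "-":
        ir_blocks = ir_blocks[::-1]
    out[IR] = Transcript(IR, ir_blocks, strand)
    return out


# ---------------------------------------------------------------------------
# Planted-ratio arithmetic


@lru_cache(maxsize=None)
def _unique_hit_positions(
    transcript: Transcript, regions: tuple[GenomicInterval, ...], read_len: int
) -> int:
    """Number of read start positions (transcript coords) whose projected
    read overlaps the given genomic regions by >= 1 nt.  Exact, by
    enumeration."""
    hits = 0
    for s in range(transcript.length - read_len + 1):
        for g_lo, g_hi in transcript.project(s, s + read_len):
            if any(
                g_lo < r.end and r.start < g_hi for r in regions
            ):
                hits += 1
                break
    return hits


def expected_density_ratio(
    model: GeneModel,
    transcripts: dict[str, Transcript],
    weights: dict[str, float],
    read_len: int,
    fl_isoform: str,
) -> float:
    """Expected unique-read density ratio pPA:FL under the mixture."""
    w_p = weights.get(PPA, 0.0)
    w_f = weights.get(fl_isoform, 0.0)
    if w_p == 0.0:
        return 0.0
    if w_f == 0.0:
        return float("inf")
    h_p = _unique_hit_positions(
        transcripts[PPA], model.unique_regions[PPA], read_len
    )
    h_f = _unique_hit_positions(
        transcripts[fl_isoform], model.unique_regions[fl_isoform], read_len
    )
    u_p = sum(r.length for r in model.unique_regions[PPA])
    u_f = sum(r.length for r in model.unique_regions[fl_isoform])
    p_p = transcripts[PPA].length - read_len + 1
    p_f = transcripts[fl_isoform].length - read_len + 1
    return (w_p * h_p / (p_p * u_p)) / (w_f * h_f / (p_f * u_f))


def ppa_fraction_for_ratio(
    model: GeneModel,
    ratio: float,
    read_len: int = 50,
    fl_weights: Optional[dict[str, float]] = None,
    fl_isoform: Optional[str] = None,
) -> float:
    """Mixture weight of the truncated transcript that plants a given
    expected pPA:FL unique-read density ratio."""
    transcripts = build_transcripts(model)
    fl_names = [n for n in model.isoforms if n != PPA]
    if fl_weights is None:
        fl_weights = {n: 1.0 / len(fl_names) for n in fl_names}
    total = sum(fl_weights.values())
    fl_weights = {n: w / total for n, w in fl_weights.items()}
    if fl_isoform is None:
        fl_isoform = fl_names[0]
    g_f = fl_weights[fl_isoform]
    if g_f <= 0:
        raise ValueError(f"reference isoform {fl_isoform!r} has zero weight")
    h_p = _unique_hit_positions(
        transcripts[PPA], model.unique_regions[PPA], read_len
    )
    h_f = _unique_hit_positions(
        transcripts[fl_isoform], model.unique_regions[fl_isoform], read_len
    )
    u_p = sum(r.length for r in model.unique_regions[PPA])
    u_f = sum(r.length for r in model.unique_regions[fl_isoform])
    p_p = transcripts[PPA].length - read_len + 1
    p_f = transcripts[fl_isoform].length - read_len + 1
    k = (h_p / (p_p * u_p)) / (h_f / (p_f * u_f))
    return ratio * g_f / (k + ratio * g_f)


# ---------------------------------------------------------------------------
# Read generation


def _mixture_weights(
    spec: SampleSpec, model: GeneModel, fl_weights: Optional[dict[str, float]]
) -> dict[str, float]:
    fl_names = [n for n in model.isoforms if n != PPA]
    if fl_weights is None:
        fl_weights = {n: 1.0 / len(fl_names) for n in fl_names}
    total = sum(fl_weights.values())
    fl_weights = {n: w / total for n, w in fl_weights.items()}
    if spec.kind in (SampleKind.NEGATIVE, SampleKind.ISOLATED_NOISE):
        return dict(fl_weights)
    if spec.kind is SampleKind.INTRON_RETENTION:
        f = spec.retention_fraction
        w = {n: (1 - f) * g for n, g in fl_weights.items()}
        w[IR] = f
        return w
    f = spec.ppa_fraction
    w = {n: (1 - f) * g for n, g in fl_weights.items()}
    w[PPA] = f
    return w


def _draw_transcript_reads(
    transcript: Transcript, n: int, read_len: int, rng: np.random.Generator
) -> tuple[list[int], list[int], list[int]]:
    """Draw ``n`` uniform-start reads; returns flat block start/end lists
    and per-read block counts."""
    length = transcript.length
    if read_len > length:
        raise ValueError(
            f"read_len {read_len} exceeds transcript {transcript.name!r} "
            f"length {length}"
        )
    starts = rng.integers(0, length - read_len + 1, size=n)
    bstarts: list[int] = []
    bends: list[int] = []
    nblocks: list[int] = []
    if transcript.strand == "+" and len(transcript.blocks) >= 1:
        cum = transcript.cumlens()
        gstart = np.array([b.start for b in transcript.blocks])
        gend = np.array([b.end for b in transcript.blocks])
        i = np.searchsorted(cum, starts, side="right") - 1
        j = np.searchsorted(cum, starts + read_len - 1, side="right") - 1
        single = i == j
        g_lo = gstart[i[single]] + (starts[single] - cum[i[single]])
        bstarts.extend(g_lo.tolist())
        bends.extend((g_lo + read_len).tolist())
        nblocks.extend([1] * int(single.sum()))
        multi = np.flatnonzero(~single)
        for s, bi, bj in zip(
            starts[multi].tolist(), i[multi].tolist(), j[multi].tolist()
        ):
            bstarts.append(int(gstart[bi] + (s - cum[bi])))
            bends.append(int(gend[bi]))
            for k in range(bi + 1, bj):
                bstarts.append(int(gstart[k]))
                bends.append(int(gend[k]))
            bstarts.append(int(gstart[bj]))
            bends.append(int(gstart[bj] + (s + read_len - cum[bj])))
            nblocks.append(bj - bi + 1)
    else:
        for s in starts:
            blocks = transcript.project(int(s), int(s) + read_len)
            for g_lo_, g_hi_ in blocks:
                bstarts.append(g_lo_)
                bends.append(g_hi_)
            nblocks.append(len(blocks))
    return bstarts, bends, nblocks


def simulate_sample(
    model: GeneModel,
    spec: SampleSpec,
    config: SimConfig,
    rng: np.random.Generator,
    transcripts: Optional[dict[str, Transcript]] = None,
) -> tuple[ReadSet, dict]:
    """Generate one sample's reads and its truth-manifest row."""
    if transcripts is None:
        transcripts = build_transcripts(model)
    weights = _mixture_weights(spec, model, config.fl_weights)
    names = sorted(weights)
    probs = np.array([weights[n] for n in names])
    counts = rng.multinomial(config.reads_per_sample, probs / probs.sum())

    bstarts: list[int] = []
    bends: list[int] = []
    nblocks: list[int] = []
    for name, n in zip(names, counts):
        if n == 0:
            continue
        bs, be, nb = _draw_transcript_reads(
            transcripts[name], int(n), config.read_len, rng
        )
        bstarts.extend(bs)
        bends.extend(be)
        nblocks.extend(nb)

    if spec.kind is SampleKind.ISOLATED_NOISE and config.noise_reads > 0:
        intron = model.target_intron
        hi = intron.end - config.read_len
        noise_starts = rng.integers(intron.start, hi + 1, size=config.noise_reads)
        for s in noise_starts:
            bstarts.append(int(s))
            bends.append(int(s) + config.read_len)
            nblocks.append(1)

    offsets = np.concatenate([[0], np.cumsum(nblocks)])
    rs = ReadSet(
        model.target_intron.chrom,
        np.array(bstarts, np.int64),
        np.array(bends, np.int64),
        offsets.astype(np.int64),
        read_ids=None,
        strand=model.strand,
    )

    if spec.kind is SampleKind.PPA_GAPPED:
        keep = np.ones(len(rs), dtype=bool)
        for lo, hi in spec.dropouts:
            region = GenomicInterval(rs.chrom, lo, hi, model.strand)
            keep &= rs.overlap_per_read(region) == 0
        rs = rs.subset(keep)

    fl_names = [n for n in model.isoforms if n != PPA]
    primary_fl = fl_names[0]
    truth = {
        "sample_id": spec.sample_id,
        "group": spec.group,
        "class": spec.kind.value,
        "retention_fraction": spec.retention_fraction,
        "ppa_fraction": spec.ppa_fraction,
        "n_reads": len(rs),
        "true_ratio": expected_density_ratio(
            model, transcripts, weights, config.read_len, primary_fl
        ),
        "ratio_reference": primary_fl,
    }
    return rs, truth


@dataclass
class CohortSim:
    """In-memory result of a cohort simulation."""

    config: SimConfig
    readsets: dict[str, ReadSet]
    manifest: pd.DataFrame


def simulate_cohort(config: SimConfig) -> CohortSim:
    """Simulate every sample of the cohort deterministically.

    Each sample gets an independent child stream spawned from the root
    seed, so the cohort output is a pure function of the configuration.
    """
    transcripts = build_transcripts(config.model)
    streams = np.random.SeedSequence(config.seed).spawn(len(config.samples))
    readsets: dict[str, ReadSet] = {}
    rows = []
    for spec, ss in zip(config.samples, streams):
        rs, truth = simulate_sample(
            config.model, spec, config, np.random.default_rng(ss), transcripts
        )
        readsets[spec.sample_id] = rs
        rows.append(truth)
    return CohortSim(config, readsets, pd.DataFrame(rows))


def write_cohort(
    sim: CohortSim, out_dir, bedgraph: bool = False
) -> dict[str, Path]:
    """Write one BED12 per sample (optionally a BEDGRAPH over the target
    intron), the truth manifest TSV, and a config echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    intron = sim.config.model.target_intron
    for sample_id, rs in sim.readsets.items():
        bed = out / f"{sample_id}.bed12"
        write_bed12(rs, bed)
        paths[sample_id] = bed
        if bedgraph:
            write_bedgraph(compute_coverage(rs, intron), out / f"{sample_id}.bedgraph")
    manifest_path = out / "truth_manifest.tsv"
    sim.manifest.to_csv(manifest_path, sep="\t", index=False)
    paths["manifest"] = manifest_path
    echo = out / "sim_config_echo.toml"
    _write_config_echo(sim.config, echo)
    paths["config"] = echo
    return paths


def _write_config_echo(config: SimConfig, path: Path) -> None:
    lines = [
        "[simulation]",
        f"gene_id = \"{config.model.gene_id}\"",
        f"reads_per_sample = {config.reads_per_sample}",
        f"read_len = {config.read_len}",
        f"noise_reads = {config.noise_reads}",
        f"seed = {config.seed}",
        "",
    ]
    for spec in config.samples:
        lines += [
            "[[sample]]",
            f"sample_id = \"{spec.sample_id}\"",
            f"group = \"{spec.group}\"",
            f"class = \"{spec.kind.value}\"",
            f"retention_fraction = {spec.retention_fraction}",
            f"ppa_fraction = {spec.ppa_fraction}",
            "dropouts = ["
            + ", ".join(f"[{lo}, {hi}]" for lo, hi in spec.dropouts)
            + "]",
            "",
        ]
    path.write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# Demo model and default cohort


def demo_gene_model() -> GeneModel:
    """A compact demonstration gene: three shared 5' exons, a 4 kb target
    intron carrying a cryptic PAS 1 kb in (region A:B = 1:3), one shared
    downstream exon and two alternative last exons distinguishing the
    full-length isoforms."""
    chrom, strand = "chr1", "+"

    def iv(lo: int, hi: int) -> GenomicInterval:
        return GenomicInterval(chrom, lo, hi, strand)

    e1, e2, e3 = iv(100, 300), iv(400, 700), iv(1000, 1200)
    e4, e5a, e5b = iv(5200, 5400), iv(6000, 7000), iv(7500, 8200)
    intron = iv(1200, 5200)
    return GeneModel(
        gene_id="DEMO1",
        strand=strand,
        isoforms={
            "FL_alpha": (e1, e2, e3, e4, e5a),
            "FL_beta": (e1, e2, e3, e4, e5b),
            PPA: (e1, e2, iv(1000, 2200)),
        },
        target_intron=intron,
        pas_position=2194,  # hexamer [2194,2200): region A = [1200,2200)
        unique_regions={
            PPA: (iv(1200, 2200),),
            "FL_alpha": (e5a,),
            "FL_beta": (e5b,),
        },
    )


def default_cohort_config(
    model: Optional[GeneModel] = None,
    seed: int = 0,
    reads_per_sample: int = 120_000,
    read_len: int = 50,
) -> SimConfig:
    """The default 16 tumor + 16 normal cohort with planted classes.

    Tumor group: three truncation-positive samples at planted density
    ratios 0.02/0.04/0.06, one gapped truncation sample, two
    intron-retention samples, two isolated-noise samples, eight clean
    samples.  Normal group: one intron-retention sample, one
    isolated-noise sample, fourteen clean samples.
    """
    model = model or demo_gene_model()
    specs: list[SampleSpec] = []

    def ppa_spec(sid: str, group: str, ratio: float, **kw) -> SampleSpec:
        frac = ppa_fraction_for_ratio(model, ratio, read_len)
        return SampleSpec(sid, group, ppa_fraction=frac, **kw)

    specs.append(ppa_spec("tumor01", "tumor", 0.02, kind=SampleKind.PPA))
    specs.append(ppa_spec("tumor02", "tumor", 0.04, kind=SampleKind.PPA))
    specs.append(ppa_spec("tumor03", "tumor", 0.06, kind=SampleKind.PPA))
    specs.append(
        ppa_spec(
            "tumor04",
            "tumor",
            0.04,
            kind=SampleKind.PPA_GAPPED,
            dropouts=((1600, 1700),),
        )
    )
    for i in (5, 6):
        specs.append(
            SampleSpec(
                f"tumor{i:02d}",
                "tumor",
                SampleKind.INTRON_RETENTION,
                retention_fraction=0.1,
            )
        )
    for i in (7, 8):
        specs.append(
            SampleSpec(f"tumor{i:02d}", "tumor", SampleKind.ISOLATED_NOISE)
        )
    for i in range(9, 17):
        specs.append(SampleSpec(f"tumor{i:02d}", "tumor", SampleKind.NEGATIVE))

    specs.append(
        SampleSpec(
            "normal01", "normal", SampleKind.INTRON_RETENTION,
            retention_fraction=0.1,
        )
    )
    specs.append(SampleSpec("normal02", "normal", SampleKind.ISOLATED_NOISE))
    for i in range(3, 17):
        specs.append(SampleSpec(f"normal{i:02d}", "normal", SampleKind.NEGATIVE))

    return SimConfig(
        model=model,
        samples=tuple(specs),
        reads_per_sample=reads_per_sample,
        read_len=read_len,
        seed=seed,
    )
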