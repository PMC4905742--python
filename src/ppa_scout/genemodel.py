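"""Gene/isoform annotation model, intron split at a cryptic poly(A) signal,
and the ORF consequence of unspliced read-through.

Coordinates are 0-based half-open (BED convention) everywhere inside the
package; GFF3 input (1-based inclusive) is converted at the I/O boundary.
"Start of the intron" and region labels are always interpreted in the
direction of transcription, so on the minus strand all boundary arithmetic
is mirrored.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

if sys.version_info >= (3, 11):
    import tomllib
else:  # pragma: no cover
    import tomli as tomllib

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "IntronSplit",
    "ModelError",
    "ModelParseError",
    "ModelValidationError",
    "PAS_HEXAMER_LEN",
    "STOP_CODONS",
    "load_gene_model",
    "split_intron",
    "find_premature_stop",
]

#: Length of a poly(A) signal hexamer (e.g. AATAAA).
PAS_HEXAMER_LEN = 6

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class ModelError(ValueError):
    """Base class for gene-model errors."""


class ModelParseError(ModelError):
    """A file could not be parsed under its declared format."""


class ModelValidationError(ModelError):
    """Parsed content violates a gene-model invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)`` on a strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ModelValidationError(f"invalid strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ModelValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        """True iff base ``pos`` lies inside the interval."""
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class IntronSplit:
    """The split of the target intron at the cryptic PAS boundary.

    ``region_A`` is the truncation-specific interval from the
    transcriptional 5' end of the intron to the PAS boundary;
    ``region_B`` is the remainder downstream.  On the minus strand
    region_A sits at the high-coordinate end of the intron.
    """

    region_A: GenomicInterval
    region_B: GenomicInterval

    @property
    def len_A(self) -> int:
        return self.region_A.length

    @property
    def len_B(self) -> int:
        return self.region_B.length

    @property
    def strand(self) -> str:
        return self.region_A.strand

    @property
    def boundary(self) -> int:
        """Genomic coordinate of the A/B split point."""
        if self.strand == "+":
            return self.region_A.end
        return self.region_A.start


@dataclass
class GeneModel:
    """Isoform structures plus the annotation facts the cascade needs.

    Parameters
    ----------
    gene_id
        Gene identifier.
    strand
        ``+`` or ``-``; all isoforms must agree.
    isoforms
        Map of isoform name to exon list.  Exons are stored in
        transcription order (ascending coordinates on ``+``, descending
        on ``-``).
    target_intron
        The intron harbouring the cryptic PAS; must coincide exactly with
        the gap between two consecutive exons of at least one isoform.
    pas_position
        Genomic position of the transcriptionally *first* base of the
        cryptic PAS hexamer.
    unique_regions
        Map of isoform name to intervals unique to that isoform
        (pairwise disjoint across isoforms), used for unambiguous read
        counting.
    """

    gene_id: str
    strand: str
    isoforms: dict[str, tuple[GenomicInterval, ...]]
    target_intron: GenomicInterval
    pas_position: int
    unique_regions: dict[str, tuple[GenomicInterval, ...]] = field(
        default_factory=dict
    )
    cleavage_offset: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.strand not in ("+", "-"):
            raise ModelValidationError(f"invalid strand {self.strand!r}")
        if not self.isoforms:
            raise ModelValidationError("gene model has no isoforms")
        self.isoforms = {
            name: self._normalize_exons(name, exons)
            for name, exons in self.isoforms.items()
        }
        self._check_target_intron()
        self._check_pas()
        self._check_unique_regions()

    def _normalize_exons(
        self, name: str, exons: Sequence[GenomicInterval]
    ) -> tuple[GenomicInterval, ...]:
        if not exons:
            raise ModelValidationError(f"isoform {name!r} has no exons")
        for ex in exons:
            if ex.strand != self.strand:
                raise ModelValidationError(
                    f"isoform {name!r} exon on wrong strand: {ex}"
                )
            if ex.chrom != exons[0].chrom:
                raise ModelValidationError(
                    f"isoform {name!r} exons on multiple chromosomes"
                )
        genomic = tuple(sorted(exons, key=lambda e: e.start))
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise ModelValidationError(
                    f"isoform {name!r} has overlapping exons {a} and {b}"
                )
        # store in transcription order
        return genomic if self.strand == "+" else genomic[::-1]

    def exons_genomic(self, name: str) -> tuple[GenomicInterval, ...]:
        """Exons of ``name`` in ascending genomic order."""
        exons = self.isoforms[name]
        return exons if self.strand == "+" else exons[::-1]

    def _check_target_intron(self) -> None:
        intron = self.target_intron
        if intron.strand != self.strand:
            raise ModelValidationError("target intron strand mismatch")
        if self.host_isoform() is None:
            raise ModelValidationError(
                f"target intron {intron.chrom}:{intron.start}-{intron.end} is "
                "not the gap between two consecutive exons of any isoform"
            )

    def host_isoform(self) -> Optional[str]:
        """Name of a full-length isoform whose exon gap equals the intron."""
        intron = self.target_intron
        for name in self.isoforms:
            genomic = self.exons_genomic(name)
            for a, b in zip(genomic, genomic[1:]):
                if a.end == intron.start and b.start == intron.end:
                    return name
        return None

    def _pas_hexamer_interval(self) -> GenomicInterval:
        if self.strand == "+":
            lo = self.pas_position
        else:
            lo = self.pas_position - PAS_HEXAMER_LEN + 1
        return GenomicInterval(
            self.target_intron.chrom, lo, lo + PAS_HEXAMER_LEN, self.strand
        )

    def _check_pas(self) -> None:
        hexamer = self._pas_hexamer_interval()
        intron = self.target_intron
        if not (intron.start <= hexamer.start and hexamer.end <= intron.end):
            raise ModelValidationError(
                f"PAS hexamer at {self.pas_position} does not lie inside the "
                f"target intron [{intron.start},{intron.end})"
            )

    def _check_unique_regions(self) -> None:
        flat: list[tuple[str, GenomicInterval]] = []
        for name, regions in self.unique_regions.items():
            if name not in self.isoforms:
                raise ModelValidationError(
                    f"unique regions declared for unknown isoform {name!r}"
                )
            for r in regions:
                flat.append((name, r))
        for i, (na, a) in enumerate(flat):
            for nb, b in flat[i + 1 :]:
                if a.overlaps(b):
                    raise ModelValidationError(
                        f"unique regions of {na!r} and {nb!r} overlap: {a} / {b}"
                    )

    # -- convenience ------------------------------------------------------
    def upstream_exons(self, name: Optional[str] = None) -> tuple[GenomicInterval, ...]:
        """Exons transcriptionally 5' of the target intron, in
        transcription order."""
        name = name or self.host_isoform()
        assert name is not None
        out = []
        for ex in self.isoforms[name]:
            if self.strand == "+" and ex.end <= self.target_intron.start:
                out.append(ex)
            elif self.strand == "-" and ex.start >= self.target_intron.end:
                out.append(ex)
        return tuple(out)


def split_intron(model: GeneModel, cleavage_offset: Optional[int] = None) -> IntronSplit:
    """Split the target intron into the truncation-specific region A and
    the downstream remainder B.

    Region A runs from the transcriptional start of the intron through the
    PAS hexamer (``pas_position + 6`` in transcript direction) plus
    ``cleavage_offset`` additional nucleotides toward an observed cleavage
    site.  Region B is the rest of the intron.
    """
    if cleavage_offset is None:
        cleavage_offset = model.cleavage_offset
    if cleavage_offset < 0:
        raise ModelValidationError("cleavage_offset must be >= 0")
    intron = model.target_intron
    shift = PAS_HEXAMER_LEN + cleavage_offset
    if model.strand == "+":
        boundary = model.pas_position + shift
    else:
        boundary = model.pas_position + 1 - shift
    if not (intron.start < boundary < intron.end):
        raise ModelValidationError(
            f"region boundary {boundary} falls outside the target intron "
            f"[{intron.start},{intron.end})"
        )
    if model.strand == "+":
        region_a = GenomicInterval(intron.chrom, intron.start, boundary, "+")
        region_b = GenomicInterval(intron.chrom, boundary, intron.end, "+")
    else:
        region_a = GenomicInterval(intron.chrom, boundary, intron.end, "-")
        region_b = GenomicInterval(intron.chrom, intron.start, boundary, "-")
    return IntronSplit(region_A=region_a, region_B=region_b)


def find_premature_stop(
    exon_tail_seq: str, intron_seq: str, frame_offset: int = 0
) -> Optional[int]:
    """Locate the first in-frame stop codon of the unspliced read-through.

    Parameters
    ----------
    exon_tail_seq
        Uppercase DNA ending at the exon-intron junction.
    intron_seq
        Uppercase DNA starting at the first intronic base.
    frame_offset
        Number of exonic nucleotides completing the codon that spans the
        junction (0 means the junction falls on a codon boundary).

    Returns
    -------
    The number of intronic nucleotides following the junction that precede
    the first base of the first in-frame stop codon (TAA/TAG/TGA), or
    ``None`` if no stop occurs before the end of ``intron_seq``.  A stop
    codon spanning the junction itself reports 0.
    """
    if not 0 <= frame_offset <= 2:
        raise ValueError("frame_offset must be 0, 1 or 2")
    if frame_offset > len(exon_tail_seq):
        raise ValueError("exon_tail_seq shorter than frame_offset")
    for seq, label in ((exon_tail_seq, "exon_tail_seq"), (intron_seq, "intron_seq")):
        if set(seq) - set("ACGT"):
            bad = sorted(set(seq) - set("ACGT"))
            raise ValueError(f"non-ACGT character(s) {bad} in {label}")
    carry = exon_tail_seq[len(exon_tail_seq) - frame_offset :] if frame_offset else ""
    frame = carry + intron_seq
    for j in range(0, len(frame) - 2, 3):
        if frame[j : j + 3] in STOP_CODONS:
            return max(0, j - frame_offset)
    return None


# ---------------------------------------------------------------------------
# Loading


def _load_config(pas_config) -> dict:
    if isinstance(pas_config, Mapping):
        return dict(pas_config)
    with open(pas_config, "rb") as fh:
        return tomllib.load(fh)


def _exons_from_bed12(path, strand: str) -> dict[str, list[GenomicInterval]]:
    from .coverage import read_bed12  # local import avoids a cycle

    readset = read_bed12(path)
    isoforms: dict[str, list[GenomicInterval]] = {}
    for rec in readset:
        if rec.read_id in isoforms:
            raise ModelParseError(
                f"{path}: duplicate isoform record {rec.read_id!r}"
            )
        isoforms[rec.read_id] = [
            GenomicInterval(b.chrom, b.start, b.end, strand) for b in rec.blocks
        ]
    return isoforms


def _exons_from_gff3(path, gene_id: str, strand: str) -> dict[str, list[GenomicInterval]]:
    """Parse exon features grouped by transcript from a GFF3 file.

    GFF3 coordinates are 1-based inclusive; converted here to 0-based
    half-open.
    """
    isoforms: dict[str, list[GenomicInterval]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ModelParseError(
                    f"{path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}"
                )
            chrom, _src, ftype, start, end, _score, fstrand, _phase, attrs = fields
            if ftype.lower() != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ModelParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start_i > end_i:
                raise ModelParseError(f"{path}:{lineno}: start > end")
            attr_map = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attr_map[k.strip()] = v.strip()
            parent = attr_map.get("Parent") or attr_map.get("ID")
            if parent is None:
                raise ModelParseError(
                    f"{path}:{lineno}: exon without Parent/ID attribute"
                )
            if fstrand != strand:
                raise ModelParseError(
                    f"{path}:{lineno}: exon strand {fstrand!r} does not match "
                    f"declared gene strand {strand!r}"
                )
            isoforms.setdefault(parent, []).append(
                GenomicInterval(chrom, start_i - 1, end_i, strand)
            )
    if not isoforms:
        raise ModelParseError(f"{path}: no exon features found")
    return isoforms


def load_gene_model(annotation_file, pas_config) -> GeneModel:
    """Load a validated :class:`GeneModel`.

    Parameters
    ----------
    annotation_file
        BED12 (one record per isoform, ``.bed``/``.bed12``) or GFF3
        (``.gff``/``.gff3``) file of isoform exon structures.
    pas_config
        TOML path or mapping with keys ``gene_id``, ``strand``,
        ``target_intron`` (``{chrom, start, end}``), ``pas_position``,
        optional ``cleavage_offset`` and ``unique_regions`` (map of
        isoform name to list of ``[start, end]`` pairs or a BED path).
    """
    cfg = _load_config(pas_config)
    for key in ("gene_id", "strand", "target_intron", "pas_position"):
        if key not in cfg:
            raise ModelValidationError(f"pas_config missing required key {key!r}")
    strand = cfg["strand"]
    ti = cfg["target_intron"]
    intron = GenomicInterval(ti["chrom"], int(ti["start"]), int(ti["end"]), strand)

    suffix = Path(str(annotation_file)).suffix.lower()
    if suffix in (".gff", ".gff3"):
        raw = _exons_from_gff3(annotation_file, cfg["gene_id"], strand)
    elif suffix in (".bed", ".bed12"):
        raw = _exons_from_bed12(annotation_file, strand)
    else:
        raise ModelParseError(
            f"unrecognized annotation extension {suffix!r} "
            "(expected .bed/.bed12/.gff/.gff3)"
        )

    unique_regions: dict[str, tuple[GenomicInterval, ...]] = {}
    for name, spec in cfg.get("unique_regions", {}).items():
        if isinstance(spec, (str, Path)):
            from .coverage import read_bed12

            regions = tuple(
                GenomicInterval(b.chrom, b.start, b.end, strand)
                for rec in read_bed12(spec)
                for b in rec.blocks
            )
        else:
            regions = tuple(
                GenomicInterval(intron.chrom, int(lo), int(hi), strand)
                for lo, hi in spec
            )
        unique_regions[name] = regions

    return GeneModel(
        gene_id=cfg["gene_id"],
        strand=strand,
        isoforms={k: tuple(v) for k, v in raw.items()},
        target_intron=intron,
        pas_position=int(cfg["pas_position"]),
        unique_regions=unique_regions,
        cleavage_offset=int(cfg.get("cleavage_offset", 0)),
    )
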