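"""Per-base coverage from blocked alignments, BEDGRAPH/BED12 I/O, and
covered-stretch / gap analytics.

Reads are carried either as individual :class:`BlockedRead` records or in
a :class:`ReadSet`, a column-store over all blocks that supports the
vectorized fast paths used by the simulator and the quantifier.  Coverage
is splice-aware: each aligned block contributes depth independently, so
the gap of a spliced read adds nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence, Union

import numpy as np

from .genemodel import GenomicInterval

__all__ = [
    "BlockedRead",
    "ReadSet",
    "CoverageTrack",
    "CoveredStretch",
    "BedgraphError",
    "compute_coverage",
    "covered_stretches",
    "read_bedgraph",
    "write_bedgraph",
    "read_bed12",
    "write_bed12",
    "reads_from_sam",
]


class BedgraphError(ValueError):
    """A BEDGRAPH file violates the format contract."""


@dataclass(frozen=True)
class BlockedRead:
    """One aligned read as an ordered list of gapless blocks."""

    read_id: str
    blocks: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError(f"read {self.read_id!r} has no blocks")
        first = self.blocks[0]
        for a, b in zip(self.blocks, self.blocks[1:]):
            if b.chrom != first.chrom or b.strand != first.strand:
                raise ValueError(
                    f"read {self.read_id!r} blocks span chromosomes/strands"
                )
            if a.end > b.start:
                raise ValueError(
                    f"read {self.read_id!r} blocks overlap or are unsorted"
                )

    @property
    def chrom(self) -> str:
        return self.blocks[0].chrom

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.blocks[0].start, self.blocks[-1].end,
            self.blocks[0].strand,
        )

    @property
    def aligned_length(self) -> int:
        return sum(b.length for b in self.blocks)


class ReadSet:
    """Column-store of blocked reads on one chromosome.

    Internally three arrays: ``block_start``/``block_end`` over all blocks
    of all reads, and ``offsets`` (length ``n_reads + 1``) delimiting each
    read's blocks.  Iteration yields :class:`BlockedRead` views.
    """

    def __init__(
        self,
        chrom: str,
        block_start: np.ndarray,
        block_end: np.ndarray,
        offsets: np.ndarray,
        read_ids: Optional[Sequence[str]] = None,
        strand: str = "+",
    ) -> None:
        self.chrom = chrom
        self.strand = strand
        self.block_start = np.asarray(block_start, dtype=np.int64)
        self.block_end = np.asarray(block_end, dtype=np.int64)
        self.offsets = np.asarray(offsets, dtype=np.int64)
        self._read_ids = list(read_ids) if read_ids is not None else None
        if self.offsets[0] != 0 or self.offsets[-1] != len(self.block_start):
            raise ValueError("malformed offsets array")
        if np.any(self.block_end <= self.block_start):
            raise ValueError("empty or inverted block")

    # -- construction -----------------------------------------------------
    @classmethod
    def from_reads(cls, reads: Iterable[BlockedRead]) -> "ReadSet":
        reads = list(reads)
        if not reads:
            return cls("", np.empty(0, np.int64), np.empty(0, np.int64), [0])
        chrom = reads[0].chrom
        strand = reads[0].blocks[0].strand
        starts, ends, offsets, ids = [], [], [0], []
        for r in reads:
            if r.chrom != chrom:
                raise ValueError("ReadSet requires a single chromosome")
            for b in r.blocks:
                starts.append(b.start)
                ends.append(b.end)
            offsets.append(len(starts))
            ids.append(r.read_id)
        return cls(chrom, np.array(starts), np.array(ends), np.array(offsets),
                   ids, strand)

    @classmethod
    def empty(cls, chrom: str = "", strand: str = "+") -> "ReadSet":
        return cls(chrom, np.empty(0, np.int64), np.empty(0, np.int64),
                   np.array([0]), [], strand)

    # -- container protocol ----------------------------------------------
    def __len__(self) -> int:
        return len(self.offsets) - 1

    def read_id(self, i: int) -> str:
        if self._read_ids is not None:
            return self._read_ids[i]
        return f"read{i:07d}"

    def read(self, i: int) -> BlockedRead:
        lo, hi = self.offsets[i], self.offsets[i + 1]
        blocks = tuple(
            GenomicInterval(self.chrom, int(s), int(e), self.strand)
            for s, e in zip(self.block_start[lo:hi], self.block_end[lo:hi])
        )
        return BlockedRead(self.read_id(i), blocks)

    def __iter__(self) -> Iterator[BlockedRead]:
        for i in range(len(self)):
            yield self.read(i)

    @property
    def n_blocks_per_read(self) -> np.ndarray:
        return np.diff(self.offsets)

    @property
    def block_read_index(self) -> np.ndarray:
        """Read index of every block (vectorized expansion of offsets)."""
        return np.repeat(np.arange(len(self)), self.n_blocks_per_read)

    def subset(self, mask_or_index: np.ndarray) -> "ReadSet":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        starts, ends, offsets = [], [], [0]
        ids = [] if self._read_ids is not None else None
        for i in idx:
            lo, hi = self.offsets[i], self.offsets[i + 1]
            starts.extend(self.block_start[lo:hi])
            ends.extend(self.block_end[lo:hi])
            offsets.append(len(starts))
            if ids is not None:
                ids.append(self._read_ids[i])
        return ReadSet(self.chrom, np.array(starts, np.int64),
                       np.array(ends, np.int64), np.array(offsets), ids,
                       self.strand)

    # -- analytics --------------------------------------------------------
    def overlap_per_read(self, region: GenomicInterval) -> np.ndarray:
        """Total aligned nucleotides of each read inside ``region``."""
        if self.chrom != region.chrom or len(self) == 0:
            return np.zeros(len(self), dtype=np.int64)
        clip = np.minimum(self.block_end, region.end) - np.maximum(
            self.block_start, region.start
        )
        np.clip(clip, 0, None, out=clip)
        out = np.zeros(len(self), dtype=np.int64)
        np.add.at(out, self.block_read_index, clip)
        return out


ReadsLike = Union[ReadSet, Iterable[BlockedRead]]


def as_readset(reads: ReadsLike) -> ReadSet:
    if isinstance(reads, ReadSet):
        return reads
    return ReadSet.from_reads(reads)


# ---------------------------------------------------------------------------
# Coverage


@dataclass
class CoverageTrack:
    """Per-base nonnegative depth over one genomic interval."""

    interval: GenomicInterval
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=np.int64)
        if self.depths.ndim != 1 or len(self.depths) != self.interval.length:
            raise ValueError("depths length must equal interval length")
        if np.any(self.depths < 0):
            raise ValueError("negative depth")

    def runs(self) -> list[tuple[int, int, int]]:
        """Run-length encoding as ``(start, end, depth)`` genomic tuples."""
        d = self.depths
        if len(d) == 0:
            return []
        change = np.flatnonzero(np.diff(d)) + 1
        bounds = np.concatenate([[0], change, [len(d)]])
        base = self.interval.start
        return [
            (base + int(lo), base + int(hi), int(d[lo]))
            for lo, hi in zip(bounds[:-1], bounds[1:])
        ]

    def subtrack(self, region: GenomicInterval) -> "CoverageTrack":
        iv = self.interval
        if region.chrom != iv.chrom or region.start < iv.start or region.end > iv.end:
            raise ValueError(
                f"region {region.chrom}:{region.start}-{region.end} not "
                f"contained in track window {iv.chrom}:{iv.start}-{iv.end}"
            )
        lo = region.start - iv.start
        return CoverageTrack(region, self.depths[lo : lo + region.length])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoverageTrack):
            return NotImplemented
        return self.interval == other.interval and np.array_equal(
            self.depths, other.depths
        )


@dataclass(frozen=True)
class CoveredStretch:
    """A maximal run of bases at or above a depth threshold."""

    interval: GenomicInterval
    min_depth_used: int


def compute_coverage(reads: ReadsLike, window: GenomicInterval) -> CoverageTrack:
    """Per-base depth over ``window``: number of read *blocks* overlapping
    each base, so splice gaps contribute zero."""
    rs = as_readset(reads)
    diff = np.zeros(window.length + 1, dtype=np.int64)
    if len(rs) and rs.chrom == window.chrom:
        lo = np.clip(rs.block_start - window.start, 0, window.length)
        hi = np.clip(rs.block_end - window.start, 0, window.length)
        keep = hi > lo
        np.add.at(diff, lo[keep], 1)
        np.add.at(diff, hi[keep], -1)
    return CoverageTrack(window, np.cumsum(diff[:-1]))


def covered_stretches(
    track: CoverageTrack, min_depth: int = 1
) -> list[CoveredStretch]:
    """Maximal runs with depth >= ``min_depth``, sorted by position."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    return [
        CoveredStretch(
            GenomicInterval(track.interval.chrom, s, e, track.interval.strand),
            min_depth,
        )
        for s, e in _threshold_runs(track, lambda d: d >= min_depth)
    ]


def zero_runs(track: CoverageTrack) -> list[GenomicInterval]:
    """Maximal zero-depth runs within the track window (incl. its ends)."""
    return [
        GenomicInterval(track.interval.chrom, s, e, track.interval.strand)
        for s, e in _threshold_runs(track, lambda d: d == 0)
    ]


def _threshold_runs(track: CoverageTrack, pred) -> list[tuple[int, int]]:
    mask = pred(track.depths)
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    base = track.interval.start
    return [
        (base + int(lo), base + int(hi))
        for lo, hi in zip(edges[::2], edges[1::2])
    ]


# ---------------------------------------------------------------------------
# BEDGRAPH I/O


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write 4-column BEDGRAPH; adjacent equal-depth runs are merged and
    zero-depth runs omitted."""
    with open(path, "w") as fh:
        for start, end, depth in track.runs():
            if depth > 0:
                fh.write(f"{track.interval.chrom}\t{start}\t{end}\t{depth}\n")


def read_bedgraph(path, window: Optional[GenomicInterval] = None) -> CoverageTrack:
    """Read a 4-column BEDGRAPH into a :class:`CoverageTrack`.

    Zero-depth bases are reconstituted inside ``window``; without a
    declared window the span from the first to the last record is used.
    Overlapping records are a format error.
    """
    records: list[tuple[str, int, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise BedgraphError(
                    f"{path}:{lineno}: expected 4 columns, got {len(fields)}"
                )
            chrom, start, end, depth = fields
            try:
                rec = (chrom, int(start), int(end), int(depth))
            except ValueError as exc:
                raise BedgraphError(f"{path}:{lineno}: non-integer field") from exc
            records.append(rec)
    if not records and window is None:
        raise BedgraphError(f"{path}: empty BEDGRAPH and no window declared")
    records.sort(key=lambda r: (r[0], r[1]))
    for (ca, sa, ea, _), (cb, sb, eb, _) in zip(records, records[1:]):
        if ca == cb and sb < ea:
            raise BedgraphError(
                f"{path}: overlapping intervals [{sa},{ea}) and [{sb},{eb})"
            )
    if window is None:
        chroms = {r[0] for r in records}
        if len(chroms) != 1:
            raise BedgraphError(
                f"{path}: multiple chromosomes; declare a window to read one"
            )
        window = GenomicInterval(records[0][0], records[0][1], records[-1][2])
    depths = np.zeros(window.length, dtype=np.int64)
    for chrom, start, end, depth in records:
        if chrom != window.chrom:
            continue
        lo = max(start, window.start) - window.start
        hi = min(end, window.end) - window.start
        if hi > lo:
            depths[lo:hi] = depth
    return CoverageTrack(window, depths)


# ---------------------------------------------------------------------------
# BED12 I/O


def read_bed12(path) -> ReadSet:
    """Read BED12 records (blockSizes/blockStarts) into a :class:`ReadSet`."""
    starts: list[int] = []
    ends: list[int] = []
    offsets = [0]
    ids: list[str] = []
    chrom: Optional[str] = None
    strand = "+"
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 BED columns, got {len(f)}"
                )
            try:
                chrom_i, chrom_start = f[0], int(f[1])
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                rel_starts = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED12 fields") from exc
            if len(sizes) != n_blocks or len(rel_starts) != n_blocks:
                raise ValueError(
                    f"{path}:{lineno}: blockCount disagrees with block lists"
                )
            if chrom is None:
                chrom = chrom_i
                strand = f[5] if f[5] in ("+", "-") else "+"
            elif chrom_i != chrom:
                raise ValueError(
                    f"{path}:{lineno}: multiple chromosomes in one read file"
                )
            for sz, rel in zip(sizes, rel_starts):
                starts.append(chrom_start + rel)
                ends.append(chrom_start + rel + sz)
            offsets.append(len(starts))
            ids.append(f[3])
    if chrom is None:
        return ReadSet.empty()
    return ReadSet(chrom, np.array(starts, np.int64), np.array(ends, np.int64),
                   np.array(offsets, np.int64), ids, strand)


def write_bed12(reads: ReadsLike, path) -> None:
    rs = as_readset(reads)
    with open(path, "w") as fh:
        for i in range(len(rs)):
            lo, hi = rs.offsets[i], rs.offsets[i + 1]
            bstarts = rs.block_start[lo:hi]
            bends = rs.block_end[lo:hi]
            start, end = int(bstarts[0]), int(bends[-1])
            sizes = ",".join(str(int(e - s)) for s, e in zip(bstarts, bends))
            rels = ",".join(str(int(s - start)) for s in bstarts)
            fh.write(
                f"{rs.chrom}\t{start}\t{end}\t{rs.read_id(i)}\t0\t{rs.strand}\t"
                f"{start}\t{end}\t0\t{hi - lo}\t{sizes}\t{rels}\n"
            )


# ---------------------------------------------------------------------------
# SAM/BAM adapter (optional; requires pysam)


def reads_from_sam(path, chrom: Optional[str] = None) -> ReadSet:
    """Convert SAM/BAM alignments to a :class:`ReadSet`.

    CIGAR M/=/X/D operations consume reference and form blocks; N (splice)
    splits blocks. Unmapped and secondary alignments are skipped.
    """
    import pysam

    reads: list[BlockedRead] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if chrom is not None and aln.reference_name != chrom:
                continue
            blocks: list[GenomicInterval] = []
            pos = aln.reference_start
            cur_start = pos
            for op, length in aln.cigartuples or []:
                if op in (0, 2, 7, 8):  # M, D, =, X consume reference
                    pos += length
                elif op == 3:  # N: splice gap closes the current block
                    if pos > cur_start:
                        blocks.append(
                            GenomicInterval(aln.reference_name, cur_start, pos)
                        )
                    pos += length
                    cur_start = pos
                # I, S, H, P consume no reference
            if pos > cur_start:
                blocks.append(GenomicInterval(aln.reference_name, cur_start, pos))
            if blocks:
                reads.append(BlockedRead(aln.query_name, tuple(blocks)))
    return ReadSet.from_reads(reads)
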