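"""Three-tier classification cascade for premature intronic
cleavage-and-polyadenylation (pPA).

Tier 1 triages samples by intronic coverage (none / isolated / sustained).
Tier 2 tests sustained samples against the intron-retention null with a
two-cell chi-square goodness-of-fit over the region A/B split.  Tier 3
requires continuous coverage across region A (at most ``max_gap_count``
gaps, each shorter than ``max_gap_nt``).  Only samples passing all three
tiers are called positive.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .coverage import (
    CoverageTrack,
    ReadsLike,
    as_readset,
    compute_coverage,
    covered_stretches,
    zero_runs,
)
from .genemodel import GeneModel, GenomicInterval, IntronSplit, split_intron

__all__ = [
    "DetectionParams",
    "Tier1",
    "Call",
    "ChiSquareResult",
    "GapReport",
    "TierResult",
    "tier1_classify",
    "assign_reads_to_regions",
    "intron_retention_chisq",
    "continuity_filter",
    "classify_sample",
]


class Tier1(str, enum.Enum):
    NO_READS = "NO_READS"
    ISOLATED = "ISOLATED"
    SUSTAINED = "SUSTAINED"


class Call(str, enum.Enum):
    PPA_POSITIVE = "PPA_POSITIVE"
    CONSISTENT_WITH_IR = "CONSISTENT_WITH_IR"
    FAILS_CONTINUITY = "FAILS_CONTINUITY"
    NEGATIVE = "NEGATIVE"


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds of the cascade.

    ``max_gap_nt``/``max_gap_count`` encode the continuity rule (every gap
    strictly shorter than 75 nt, at most 4 gaps); a gap of exactly 75 nt
    fails.  ``min_stretch_nt``/``min_stretch_reads`` quantify the tier-1
    notion of a sustained stretch of overlapping reads.
    """

    alpha: float = 0.05
    max_gap_nt: int = 75
    max_gap_count: int = 4
    min_stretch_nt: int = 100
    min_stretch_reads: int = 5
    min_depth: int = 1
    yates: bool = False
    count_mode: str = "reads"  # or "bases"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.max_gap_nt < 1:
            raise ValueError("max_gap_nt must be >= 1")
        if self.max_gap_count < 0:
            raise ValueError("max_gap_count must be >= 0")
        if self.count_mode not in ("reads", "bases"):
            raise ValueError("count_mode must be 'reads' or 'bases'")


@dataclass(frozen=True)
class ChiSquareResult:
    """Two-cell goodness-of-fit outcome against the intron-retention null."""

    obs_A: float
    obs_B: float
    exp_A: float
    exp_B: float
    statistic: float
    p_value: float
    reject_null: bool
    alpha: float


@dataclass(frozen=True)
class GapReport:
    """Zero-coverage gaps inside region A and the continuity verdict."""

    gaps: tuple[GenomicInterval, ...]
    passes: bool
    max_gap_nt: int
    max_gap_count: int

    @property
    def n_gaps(self) -> int:
        return len(self.gaps)

    @property
    def max_gap_len(self) -> int:
        return max((g.length for g in self.gaps), default=0)


@dataclass
class TierResult:
    """Per-sample cascade verdict."""

    sample_id: str
    tier1: Tier1
    tier2: Optional[ChiSquareResult] = None
    tier3: Optional[GapReport] = None
    call: Call = Call.NEGATIVE
    group: Optional[str] = None

    def to_row(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "group": self.group if self.group is not None else "",
            "tier1": self.tier1.value,
            "obs_A": self.tier2.obs_A if self.tier2 else "",
            "obs_B": self.tier2.obs_B if self.tier2 else "",
            "chi2": f"{self.tier2.statistic:.6g}" if self.tier2 else "",
            "p": f"{self.tier2.p_value:.6g}" if self.tier2 else "",
            "n_gaps": self.tier3.n_gaps if self.tier3 else "",
            "max_gap_len": self.tier3.max_gap_len if self.tier3 else "",
            "call": self.call.value,
        }


# ---------------------------------------------------------------------------
# Tier 1


def tier1_classify(
    track: CoverageTrack,
    intron: GenomicInterval,
    params: DetectionParams = DetectionParams(),
) -> Tier1:
    """Triage the intronic coverage pattern.

    ``NO_READS`` when every intronic base has zero depth; ``SUSTAINED``
    when some covered stretch is at least ``min_stretch_nt`` long and
    reaches depth ``min_stretch_reads`` somewhere inside; ``ISOLATED``
    otherwise.
    """
    sub = track.subtrack(intron)
    if not sub.depths.any():
        return Tier1.NO_READS
    for stretch in covered_stretches(sub, params.min_depth):
        if stretch.interval.length < params.min_stretch_nt:
            continue
        peak = sub.subtrack(stretch.interval).depths.max()
        if peak >= params.min_stretch_reads:
            return Tier1.SUSTAINED
    return Tier1.ISOLATED


# ---------------------------------------------------------------------------
# Tier 2


def assign_reads_to_regions(
    reads: ReadsLike, split: IntronSplit
) -> tuple[int, int]:
    """Count intron-overlapping reads per region by the midpoint rule.

    Each read with at least one intronic base is assigned to exactly one
    region according to the midpoint of the hull of its intronic
    footprint; a midpoint exactly on the A/B boundary goes to region A.
    Reads with no intronic bases are ignored.
    """
    rs = as_readset(reads)
    intron = _intron_of(split)
    if len(rs) == 0 or rs.chrom != intron.chrom:
        return 0, 0
    clip_lo = np.maximum(rs.block_start, intron.start)
    clip_hi = np.minimum(rs.block_end, intron.end)
    has = clip_hi > clip_lo
    ridx = rs.block_read_index
    # footprint hull per read over intronic blocks only
    first = np.full(len(rs), np.iinfo(np.int64).max, dtype=np.int64)
    last = np.full(len(rs), np.iinfo(np.int64).min, dtype=np.int64)
    np.minimum.at(first, ridx[has], clip_lo[has])
    np.maximum.at(last, ridx[has], clip_hi[has])
    overlapping = last > first
    mid = (first[overlapping] + last[overlapping]) / 2.0
    if split.strand == "+":
        in_a = mid <= split.boundary
    else:
        in_a = mid >= split.boundary
    obs_a = int(np.count_nonzero(in_a))
    return obs_a, int(np.count_nonzero(overlapping)) - obs_a


def _intron_of(split: IntronSplit) -> GenomicInterval:
    lo = min(split.region_A.start, split.region_B.start)
    hi = max(split.region_A.end, split.region_B.end)
    return GenomicInterval(split.region_A.chrom, lo, hi, split.strand)


def intron_retention_chisq(
    obs_A: float,
    obs_B: float,
    split: IntronSplit,
    alpha: float = 0.05,
    yates: bool = False,
) -> ChiSquareResult:
    """Chi-square goodness-of-fit of the observed A/B read counts against
    the intron-retention null (reads uniform over the intron).

    Expected counts are proportional to region lengths; the statistic is
    the plain two-cell Pearson sum with 1 degree of freedom (optional
    Yates continuity correction).
    """
    n = obs_A + obs_B
    if n <= 0:
        raise ValueError("no intronic reads: obs_A + obs_B must be > 0")
    len_a, len_b = split.len_A, split.len_B
    if len_a <= 0 or len_b <= 0:
        raise ValueError("zero-length region in intron split")
    total_len = len_a + len_b
    exp_a = n * len_a / total_len
    exp_b = n * len_b / total_len
    if yates:
        stat = ((abs(obs_A - exp_a) - 0.5) ** 2) / exp_a + (
            (abs(obs_B - exp_b) - 0.5) ** 2
        ) / exp_b
    else:
        stat = (obs_A - exp_a) ** 2 / exp_a + (obs_B - exp_b) ** 2 / exp_b
    p = float(stats.chi2.sf(stat, df=1))
    return ChiSquareResult(
        obs_A=obs_A,
        obs_B=obs_B,
        exp_A=exp_a,
        exp_B=exp_b,
        statistic=float(stat),
        p_value=p,
        reject_null=bool(p < alpha),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Tier 3


def continuity_filter(
    track: CoverageTrack,
    region_A: GenomicInterval,
    params: DetectionParams = DetectionParams(),
) -> GapReport:
    """Gap scan over region A.

    Gaps are maximal zero-depth runs within region A, including uncovered
    ends.  The sample passes iff every gap is strictly shorter than
    ``max_gap_nt`` and there are at most ``max_gap_count`` gaps.
    """
    gaps = tuple(zero_runs(track.subtrack(region_A)))
    passes = len(gaps) <= params.max_gap_count and all(
        g.length < params.max_gap_nt for g in gaps
    )
    return GapReport(
        gaps=gaps,
        passes=passes,
        max_gap_nt=params.max_gap_nt,
        max_gap_count=params.max_gap_count,
    )


# ---------------------------------------------------------------------------
# Final call


def _final_call(
    tier1: Tier1,
    tier2: Optional[ChiSquareResult],
    tier3: Optional[GapReport],
) -> Call:
    """Pure decision table combining the three tier outputs."""
    if tier1 is not Tier1.SUSTAINED:
        return Call.NEGATIVE
    assert tier2 is not None
    if not tier2.reject_null:
        return Call.CONSISTENT_WITH_IR
    assert tier3 is not None
    return Call.PPA_POSITIVE if tier3.passes else Call.FAILS_CONTINUITY


def classify_sample(
    reads: Optional[ReadsLike],
    model: GeneModel,
    params: DetectionParams = DetectionParams(),
    sample_id: str = "sample",
    track: Optional[CoverageTrack] = None,
    group: Optional[str] = None,
) -> TierResult:
    """Run the full cascade on one sample.

    Either blocked ``reads`` or a precomputed coverage ``track`` spanning
    the target intron must be provided.  With only a track, tier-2 counts
    fall back to per-base counting (``count_mode='bases'`` semantics).
    """
    if reads is None and track is None:
        raise ValueError("provide reads and/or a coverage track")
    intron = model.target_intron
    split = split_intron(model)
    rs = as_readset(reads) if reads is not None else None
    if track is None:
        track = compute_coverage(rs, intron)

    tier1 = tier1_classify(track, intron, params)
    tier2: Optional[ChiSquareResult] = None
    tier3: Optional[GapReport] = None
    if tier1 is Tier1.SUSTAINED:
        if rs is not None and params.count_mode == "reads":
            obs_a, obs_b = assign_reads_to_regions(rs, split)
        else:
            obs_a = int(track.subtrack(split.region_A).depths.sum())
            obs_b = int(track.subtrack(split.region_B).depths.sum())
        tier2 = intron_retention_chisq(
            obs_a, obs_b, split, alpha=params.alpha, yates=params.yates
        )
        if tier2.reject_null:
            tier3 = continuity_filter(track, split.region_A, params)
    return TierResult(
        sample_id=sample_id,
        tier1=tier1,
        tier2=tier2,
        tier3=tier3,
        call=_final_call(tier1, tier2, tier3),
        group=group,
    )
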