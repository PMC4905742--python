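"""Length-corrected relative isoform quantification and cohort-level
sequencing-depth comparison.

Relative expression of the truncated isoform is computed from reads that
map uniquely to each isoform's declared unique regions, corrected by the
total unique-region length (reads per nucleotide), and reported as density
ratios of the truncated isoform over each full-length isoform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .coverage import ReadsLike, as_readset
from .genemodel import GeneModel

__all__ = [
    "IsoformQuant",
    "DepthComparison",
    "unique_region_counts",
    "relative_expression",
    "upper_quartile_normalize",
    "median_fold_change",
]

PPA_ISOFORM = "pPA"


@dataclass
class IsoformQuant:
    """Unique-region read counts, lengths, densities and density ratios."""

    counts: dict[str, int]
    unique_lengths: dict[str, int]
    densities: dict[str, float] = field(init=False)
    ratios: dict[tuple[str, str], Optional[float]] = field(init=False)
    ppa_isoform: str = PPA_ISOFORM

    def __post_init__(self) -> None:
        for name, length in self.unique_lengths.items():
            if length <= 0:
                raise ValueError(f"unique length of {name!r} must be > 0")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative read count")
        self.densities = {
            name: self.counts.get(name, 0) / length
            for name, length in self.unique_lengths.items()
        }
        self.ratios = {}
        ppa_density = self.densities.get(self.ppa_isoform)
        if ppa_density is None:
            raise ValueError(
                f"no unique length declared for isoform {self.ppa_isoform!r}"
            )
        for name, density in self.densities.items():
            if name == self.ppa_isoform:
                continue
            if density > 0:
                self.ratios[(self.ppa_isoform, name)] = ppa_density / density
            else:
                warnings.warn(
                    f"isoform {name!r} has zero unique-read density; "
                    "ratio reported as missing",
                    stacklevel=2,
                )
                self.ratios[(self.ppa_isoform, name)] = None


@dataclass
class DepthComparison:
    """Matched-group normalized expression with the median fold change."""

    case_values: np.ndarray
    control_values: np.ndarray
    median_fold_change: float
    n_pairs_used: int
    method: str = "median_of_ratios"


def unique_region_counts(
    reads: ReadsLike,
    model: GeneModel,
    min_overlap: int = 1,
    isoforms: Optional[Sequence[str]] = None,
) -> dict[str, int]:
    """Count reads mapping uniquely to each isoform.

    A read counts for isoform ``X`` iff at least ``min_overlap`` aligned
    nucleotides of its blocks fall inside ``X``'s declared unique regions.
    Because unique regions are pairwise disjoint across isoforms, a read
    meeting the threshold for two isoforms is geometrically anomalous; it
    is dropped with a warning so that no read is ever counted twice.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    names = list(isoforms) if isoforms is not None else list(model.unique_regions)
    for name in names:
        if name not in model.unique_regions or not model.unique_regions[name]:
            raise ValueError(f"no unique regions declared for isoform {name!r}")
    rs = as_readset(reads)
    if len(rs) == 0:
        return {name: 0 for name in names}
    hits = np.zeros((len(names), len(rs)), dtype=bool)
    for i, name in enumerate(names):
        overlap = np.zeros(len(rs), dtype=np.int64)
        for region in model.unique_regions[name]:
            overlap += rs.overlap_per_read(region)
        hits[i] = overlap >= min_overlap
    n_hit = hits.sum(axis=0)
    ambiguous = int(np.count_nonzero(n_hit > 1))
    if ambiguous:
        warnings.warn(
            f"{ambiguous} read(s) met the overlap threshold for more than "
            "one isoform and were excluded",
            stacklevel=2,
        )
        hits[:, n_hit > 1] = False
    return {name: int(hits[i].sum()) for i, name in enumerate(names)}


def relative_expression(
    counts: Mapping[str, int],
    unique_lengths: Optional[Mapping[str, int]] = None,
    model: Optional[GeneModel] = None,
    ppa_isoform: str = PPA_ISOFORM,
) -> IsoformQuant:
    """Build an :class:`IsoformQuant` from counts and unique-region lengths.

    ``unique_lengths`` may be omitted when a ``model`` is given, in which
    case lengths are the summed declared unique-region lengths.
    """
    if unique_lengths is None:
        if model is None:
            raise ValueError("provide unique_lengths or a model")
        unique_lengths = {
            name: sum(r.length for r in regions)
            for name, regions in model.unique_regions.items()
        }
    return IsoformQuant(
        counts=dict(counts),
        unique_lengths=dict(unique_lengths),
        ppa_isoform=ppa_isoform,
    )


def upper_quartile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Upper-quartile normalization of an expression matrix.

    ``values`` has genes as rows and samples as columns.  Each sample is
    divided by the 75th percentile of its nonzero values and rescaled by
    the cohort mean upper quartile, so identical samples are unchanged up
    to a global scale and a uniformly scaled sample becomes equal to its
    unscaled twin.
    """
    if values.shape[1] == 0:
        raise ValueError("no samples to normalize")
    uqs = {}
    for sample in values.columns:
        col = values[sample].to_numpy(dtype=float)
        positive = col[col > 0]
        if positive.size == 0:
            raise ValueError(f"sample {sample!r} is all-zero")
        if positive.size < 4:
            raise ValueError(
                f"sample {sample!r} has fewer than 4 positive values"
            )
        uqs[sample] = float(np.percentile(positive, 75))
    scale = float(np.mean(list(uqs.values())))
    return values / pd.Series(uqs) * scale


def median_fold_change(
    case_values: Sequence[float],
    control_values: Sequence[float],
    method: str = "median_of_ratios",
) -> DepthComparison:
    """Median fold change of matched case/control expression values.

    Pairs whose control (or case) value is not strictly positive are
    dropped with a warning.  ``method`` is either ``median_of_ratios``
    (default; median over per-pair case/control ratios) or
    ``ratio_of_medians``.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.shape != control.shape:
        raise ValueError("case and control value arrays must be paired")
    if method not in ("median_of_ratios", "ratio_of_medians"):
        raise ValueError(f"unknown method {method!r}")
    ok = (control > 0) & (case > 0)
    dropped = int(np.count_nonzero(~ok))
    if dropped:
        warnings.warn(
            f"{dropped} pair(s) with nonpositive values dropped", stacklevel=2
        )
    if not ok.any():
        raise ValueError("no usable pairs")
    if method == "median_of_ratios":
        fold = float(np.median(case[ok] / control[ok]))
    else:
        fold = float(np.median(case[ok]) / np.median(control[ok]))
    return DepthComparison(
        case_values=case[ok],
        control_values=control[ok],
        median_fold_change=fold,
        n_pairs_used=int(ok.sum()),
        method=method,
    )
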