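"""Cohort summary (tier funnel) and pipeline orchestration."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .detect import (
    Call,
    DetectionParams,
    Tier1,
    TierResult,
    classify_sample,
)
from .genemodel import GeneModel
from .quantify import relative_expression, unique_region_counts
from .simdata import (
    CohortSim,
    SimConfig,
    default_cohort_config,
    simulate_cohort,
    write_cohort,
)

__all__ = ["GroupSummary", "CohortSummary", "summarize_cohort", "run_pipeline"]

logger = logging.getLogger("ppa_scout")


@dataclass(frozen=True)
class GroupSummary:
    """Tier funnel for one sample group."""

    group: str
    n_samples: int
    n_tier1_sustained: int
    n_tier2_reject: int
    n_tier3_pass: int

    def __post_init__(self) -> None:
        if not (
            self.n_tier3_pass
            <= self.n_tier2_reject
            <= self.n_tier1_sustained
            <= self.n_samples
        ):
            raise ValueError(
                f"non-monotone funnel for group {self.group!r}: "
                f"{self.n_tier3_pass} <= {self.n_tier2_reject} <= "
                f"{self.n_tier1_sustained} <= {self.n_samples} violated"
            )

    @property
    def percent_positive(self) -> float:
        return 100.0 * self.n_tier3_pass / self.n_samples


@dataclass
class CohortSummary:
    groups: dict[str, GroupSummary]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.groups.values():
            row = asdict(g)
            row["percent_positive"] = round(g.percent_positive, 1)
            rows.append(row)
        return pd.DataFrame(rows)


def summarize_cohort(
    results: Sequence[TierResult],
    groups: Optional[Mapping[str, str]] = None,
) -> CohortSummary:
    """Tier funnel per group from per-sample cascade results.

    ``groups`` maps sample_id to a free-form group label; omitted samples
    fall back to the result's own ``group`` field or ``"all"``.
    """
    seen: set[str] = set()
    per_group: dict[str, list[TierResult]] = {}
    for res in results:
        if res.sample_id in seen:
            raise ValueError(f"duplicate sample_id {res.sample_id!r}")
        seen.add(res.sample_id)
        if groups is not None and res.sample_id in groups:
            label = groups[res.sample_id]
        else:
            label = res.group or "all"
        per_group.setdefault(label, []).append(res)

    out: dict[str, GroupSummary] = {}
    for label, items in per_group.items():
        sustained = sum(1 for r in items if r.tier1 is Tier1.SUSTAINED)
        reject = sum(
            1 for r in items if r.tier2 is not None and r.tier2.reject_null
        )
        positive = sum(1 for r in items if r.call is Call.PPA_POSITIVE)
        out[label] = GroupSummary(
            group=label,
            n_samples=len(items),
            n_tier1_sustained=sustained,
            n_tier2_reject=reject,
            n_tier3_pass=positive,
        )
    return CohortSummary(groups=out)


def run_pipeline(
    out_dir,
    sim_config: Optional[SimConfig] = None,
    model: Optional[GeneModel] = None,
    params: Optional[DetectionParams] = None,
    seed: Optional[int] = None,
    write_reads: bool = True,
) -> dict:
    """Simulate a cohort, classify and quantify every sample, and write
    the artifact set (per-sample TSV, quantification TSV, summary
    JSON/TSV, log).  Deterministic given the configuration and seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        params = params or DetectionParams()
        if sim_config is None:
            sim_config = default_cohort_config(
                model=model, seed=0 if seed is None else seed
            )
        elif seed is not None and seed != sim_config.seed:
            raise ValueError("seed given twice with conflicting values")
        model = sim_config.model
        logger.info("detection params: %s", params)
        logger.info("simulating cohort of %d samples (seed=%d)",
                    len(sim_config.samples), sim_config.seed)
        sim: CohortSim = simulate_cohort(sim_config)
        if write_reads:
            write_cohort(sim, out / "reads")

        results: list[TierResult] = []
        quant_rows = []
        spec_by_id = {s.sample_id: s for s in sim_config.samples}
        for sample_id, rs in sim.readsets.items():
            spec = spec_by_id[sample_id]
            res = classify_sample(
                rs, model, params, sample_id=sample_id, group=spec.group
            )
            logger.info(
                "sample %s: tier1=%s p=%s call=%s",
                sample_id,
                res.tier1.value,
                f"{res.tier2.p_value:.3g}" if res.tier2 else "-",
                res.call.value,
            )
            results.append(res)
            counts = unique_region_counts(rs, model)
            quant = relative_expression(counts, model=model)
            row = {"sample_id": sample_id, "group": spec.group}
            row.update({f"count_{k}": v for k, v in quant.counts.items()})
            row.update(
                {f"density_{k}": v for k, v in quant.densities.items()}
            )
            for (ppa, fl), ratio in quant.ratios.items():
                row[f"ratio_{ppa}_vs_{fl}"] = ratio
            quant_rows.append(row)

        per_sample = pd.DataFrame([r.to_row() for r in results])
        per_sample.to_csv(out / "classification.tsv", sep="\t", index=False)
        pd.DataFrame(quant_rows).to_csv(
            out / "quantification.tsv", sep="\t", index=False
        )
        summary = summarize_cohort(results)
        summary.to_frame().to_csv(out / "summary.tsv", sep="\t", index=False)
        summary_json = {
            g: {
                "n_samples": s.n_samples,
                "n_tier1_sustained": s.n_tier1_sustained,
                "n_tier2_reject": s.n_tier2_reject,
                "n_tier3_pass": s.n_tier3_pass,
                "percent_positive": round(s.percent_positive, 1),
            }
            for g, s in summary.groups.items()
        }
        (out / "summary.json").write_text(
            json.dumps(summary_json, indent=2) + "\n"
        )
        logger.info("summary: %s", summary_json)
        return {
            "results": results,
            "summary": summary,
            "manifest": sim.manifest,
            "out_dir": out,
        }
    finally:
        logger.removeHandler(handler)
        handler.close()
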