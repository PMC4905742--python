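import itertools
import math

import numpy as np
import pytest

from ppa_scout.coverage import BlockedRead, CoverageTrack, compute_coverage
from ppa_scout.detect import (
    Call,
    ChiSquareResult,
    DetectionParams,
    GapReport,
    Tier1,
    _final_call,
    assign_reads_to_regions,
    classify_sample,
    continuity_filter,
    intron_retention_chisq,
    tier1_classify,
)
from ppa_scout.genemodel import GenomicInterval, IntronSplit
from ppa_scout.simdata import (
    SampleKind,
    SampleSpec,
    SimConfig,
    demo_gene_model,
    simulate_sample,
)

from conftest import iv, random_blocked_reads, single_block_read


def make_split(len_a, len_b, start=1000, strand="+"):
    if strand == "+":
        return IntronSplit(
            iv(start, start + len_a, strand=strand),
            iv(start + len_a, start + len_a + len_b, strand=strand),
        )
    return IntronSplit(
        iv(start + len_b, start + len_b + len_a, strand=strand),
        iv(start, start + len_b, strand=strand),
    )


# ---------------------------------------------------------------------------
# tier 1


def test_tier1_no_reads(intron):
    track = CoverageTrack(intron, np.zeros(intron.length, int))
    assert tier1_classify(track, intron) is Tier1.NO_READS


def test_tier1_isolated_reads(intron):
    reads = [
        single_block_read("a", 1300, 1350),
        single_block_read("b", 2500, 2550),
        single_block_read("c", 4000, 4050),
    ]
    track = compute_coverage(reads, intron)
    assert tier1_classify(track, intron) is Tier1.ISOLATED


def test_tier1_long_but_shallow_stretch_is_isolated(intron):
    # 200 nt covered but peak depth 2 < min_stretch_reads
    reads = [
        single_block_read("a", 1300, 1500),
        single_block_read("b", 1350, 1450),
    ]
    track = compute_coverage(reads, intron)
    assert tier1_classify(track, intron) is Tier1.ISOLATED


def test_tier1_sustained_on_simulated_ir(model):
    params = DetectionParams()
    spec = SampleSpec("s", "g", SampleKind.INTRON_RETENTION, retention_fraction=0.2)
    config = SimConfig(model=model, samples=(spec,), reads_per_sample=20_000)
    hits = 0
    for seed in range(100):
        rs, _ = simulate_sample(model, spec, config, np.random.default_rng(seed))
        track = compute_coverage(rs, model.target_intron)
        if tier1_classify(track, model.target_intron, params) is Tier1.SUSTAINED:
            hits += 1
    assert hits == 100


def test_tier1_window_must_contain_intron(intron):
    track = CoverageTrack(iv(1300, 1400), np.ones(100, int))
    with pytest.raises(ValueError):
        tier1_classify(track, intron)


# ---------------------------------------------------------------------------
# read-to-region assignment


def test_assign_read_wholly_in_region_a():
    split = make_split(1000, 3000)
    assert assign_reads_to_regions([single_block_read("a", 1100, 1150)], split) == (1, 0)


def test_assign_straddler_with_midpoint_in_b():
    split = make_split(1000, 3000)  # boundary at 2000
    read = single_block_read("a", 1990, 2050)  # midpoint 2020
    assert assign_reads_to_regions([read], split) == (0, 1)


def test_assign_midpoint_on_boundary_goes_to_a():
    split = make_split(1000, 3000)
    read = single_block_read("a", 1975, 2025)  # midpoint exactly 2000
    assert assign_reads_to_regions([read], split) == (1, 0)


def test_assign_exonic_read_ignored():
    split = make_split(1000, 3000)
    assert assign_reads_to_regions([single_block_read("a", 100, 150)], split) == (0, 0)


def brute_force_assign(reads, split):
    intron_lo = min(split.region_A.start, split.region_B.start)
    intron_hi = max(split.region_A.end, split.region_B.end)
    obs_a = obs_b = 0
    for read in reads:
        positions = sorted(
            p
            for b in read.blocks
            for p in range(max(b.start, intron_lo), min(b.end, intron_hi))
        )
        if not positions:
            continue
        mid = (positions[0] + positions[-1] + 1) / 2
        if split.strand == "+":
            in_a = mid <= split.region_A.end
        else:
            in_a = mid >= split.region_A.start
        if in_a:
            obs_a += 1
        else:
            obs_b += 1
    return obs_a, obs_b


@pytest.mark.parametrize("strand", ["+", "-"])
def test_assign_matches_bruteforce(strand):
    split = make_split(700, 2100, strand=strand)
    rng = np.random.default_rng(17)
    reads = random_blocked_reads(rng, 2000, 500, 4500)
    got = assign_reads_to_regions(reads, split)
    assert got == brute_force_assign(reads, split)
    lo = min(split.region_A.start, split.region_B.start)
    hi = max(split.region_A.end, split.region_B.end)
    intron_overlapping = sum(
        1 for r in reads if any(b.start < hi and b.end > lo for b in r.blocks)
    )
    assert got[0] + got[1] == intron_overlapping


# ---------------------------------------------------------------------------
# chi-square


def test_chisq_observed_equals_expected():
    split = make_split(1000, 3000)
    res = intron_retention_chisq(25, 75, split)
    assert res.statistic == 0
    assert res.p_value == 1
    assert not res.reject_null


def test_chisq_hand_example():
    split = make_split(1000, 3000)
    res = intron_retention_chisq(50, 50, split)
    assert res.exp_A == 25 and res.exp_B == 75
    expected_stat = 25**2 / 25 + 25**2 / 75
    assert res.statistic == pytest.approx(expected_stat, abs=1e-12)
    # df-1 closed form: p = erfc(sqrt(x/2))
    assert res.p_value == pytest.approx(math.erfc(math.sqrt(expected_stat / 2)),
                                        rel=1e-9)
    assert res.p_value == pytest.approx(7.7e-9, rel=0.05)
    assert res.reject_null


def test_chisq_all_reads_one_region():
    split = make_split(2000, 2000)
    res = intron_retention_chisq(0, 100, split)
    assert res.statistic == pytest.approx(100.0)
    assert res.reject_null


def test_chisq_requires_reads():
    split = make_split(1000, 3000)
    with pytest.raises(ValueError, match="no intronic reads"):
        intron_retention_chisq(0, 0, split)


def test_chisq_expected_counts_sum_to_observed():
    split = make_split(1234, 4321)
    res = intron_retention_chisq(17, 40, split)
    assert res.exp_A + res.exp_B == pytest.approx(57)


# ---------------------------------------------------------------------------
# continuity filter


def _track_with_gaps(region, gaps):
    depths = np.full(region.length, 10, dtype=int)
    for lo, hi in gaps:
        depths[lo - region.start : hi - region.start] = 0
    return CoverageTrack(region, depths)


REGION_A = iv(1200, 2200)


def test_continuity_full_coverage_passes():
    report = continuity_filter(_track_with_gaps(REGION_A, []), REGION_A)
    assert report.n_gaps == 0 and report.passes


def test_continuity_single_80nt_gap_fails():
    report = continuity_filter(
        _track_with_gaps(REGION_A, [(1500, 1580)]), REGION_A
    )
    assert report.max_gap_len == 80
    assert not report.passes


def test_continuity_exactly_75nt_gap_fails():
    report = continuity_filter(
        _track_with_gaps(REGION_A, [(1500, 1575)]), REGION_A
    )
    assert not report.passes


def test_continuity_four_small_gaps_pass_five_fail():
    four = [(1300 + 100 * k, 1310 + 100 * k) for k in range(4)]
    five = [(1300 + 100 * k, 1310 + 100 * k) for k in range(5)]
    assert continuity_filter(_track_with_gaps(REGION_A, four), REGION_A).passes
    assert not continuity_filter(_track_with_gaps(REGION_A, five), REGION_A).passes


def test_continuity_counts_uncovered_ends():
    report = continuity_filter(
        _track_with_gaps(REGION_A, [(1200, 1210), (2190, 2200)]), REGION_A
    )
    assert report.n_gaps == 2
    assert report.gaps[0].start == 1200 and report.gaps[-1].end == 2200


def brute_force_gap_report(track, region, params):
    depths = track.subtrack(region).depths
    gaps, run = [], 0
    for depth in depths:
        if depth == 0:
            run += 1
        elif run:
            gaps.append(run)
            run = 0
    if run:
        gaps.append(run)
    passes = len(gaps) <= params.max_gap_count and all(
        g < params.max_gap_nt for g in gaps
    )
    return gaps, passes


@pytest.mark.parametrize("seed", range(30))
def test_continuity_matches_bruteforce_scan(seed):
    rng = np.random.default_rng(seed)
    params = DetectionParams()
    depths = (rng.random(1000) > 0.15).astype(int) * rng.integers(
        1, 5, size=1000
    )
    track = CoverageTrack(REGION_A, depths)
    report = continuity_filter(track, REGION_A, params)
    gaps, passes = brute_force_gap_report(track, REGION_A, params)
    assert [g.length for g in report.gaps] == gaps
    assert report.passes == passes


# ---------------------------------------------------------------------------
# final call decision table


def _chi(reject):
    return ChiSquareResult(10, 10, 5, 15, 1.0, 0.01 if reject else 0.5,
                           reject, 0.05)


def _gap(passes):
    return GapReport((), passes, 75, 4) if passes else GapReport(
        (iv(0, 100),), passes, 75, 4
    )


def test_final_call_decision_table():
    for tier1 in Tier1:
        if tier1 is not Tier1.SUSTAINED:
            assert _final_call(tier1, None, None) is Call.NEGATIVE
            continue
        assert _final_call(tier1, _chi(False), None) is Call.CONSISTENT_WITH_IR
        assert _final_call(tier1, _chi(True), _gap(True)) is Call.PPA_POSITIVE
        assert _final_call(tier1, _chi(True), _gap(False)) is Call.FAILS_CONTINUITY


def test_tier_result_invariants_in_classify(model):
    spec = SampleSpec("s", "g", SampleKind.NEGATIVE)
    config = SimConfig(model=model, samples=(spec,), reads_per_sample=5000)
    rs, _ = simulate_sample(model, spec, config, np.random.default_rng(0))
    res = classify_sample(rs, model, sample_id="s")
    assert res.tier1 is Tier1.NO_READS
    assert res.tier2 is None and res.tier3 is None
    assert res.call is Call.NEGATIVE


# ---------------------------------------------------------------------------
# classify_sample on planted samples


def _simulate_and_classify(model, spec, reads_per_sample=120_000, seed=0):
    config = SimConfig(model=model, samples=(spec,),
                       reads_per_sample=reads_per_sample)
    rs, _ = simulate_sample(model, spec, config, np.random.default_rng(seed))
    return classify_sample(rs, model, sample_id=spec.sample_id)


def test_classify_planted_ppa(model):
    spec = SampleSpec("p", "t", SampleKind.PPA, ppa_fraction=0.02)
    assert _simulate_and_classify(model, spec).call is Call.PPA_POSITIVE


def test_classify_planted_ir(model):
    spec = SampleSpec("i", "t", SampleKind.INTRON_RETENTION,
                      retention_fraction=0.1)
    assert _simulate_and_classify(model, spec).call is Call.CONSISTENT_WITH_IR


def test_classify_planted_gapped_ppa(model):
    spec = SampleSpec("g", "t", SampleKind.PPA_GAPPED, ppa_fraction=0.02,
                      dropouts=((1600, 1700),))
    assert _simulate_and_classify(model, spec).call is Call.FAILS_CONTINUITY


def test_classify_base_mode_from_track_only(model):
    spec = SampleSpec("p", "t", SampleKind.PPA, ppa_fraction=0.02)
    config = SimConfig(model=model, samples=(spec,), reads_per_sample=120_000)
    rs, _ = simulate_sample(model, spec, config, np.random.default_rng(1))
    track = compute_coverage(rs, model.target_intron)
    res = classify_sample(None, model, sample_id="p", track=track)
    assert res.call is Call.PPA_POSITIVE


def test_detection_params_validation():
    with pytest.raises(ValueError):
        DetectionParams(alpha=1.5)
    with pytest.raises(ValueError):
        DetectionParams(max_gap_nt=0)
    with pytest.raises(ValueError):
        DetectionParams(count_mode="bogus")
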