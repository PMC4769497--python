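"""Statistics engine: per-read accounting, finalization, and the oracle check."""

import numpy as np
import pytest

from poremap.fast5 import BasecalledRead, ChannelInfo, Fast5Record, TrackingInfo
from poremap.stats import (
    ReadTypeStats,
    RunStats,
    finalize,
    finalize_read_type,
    gc_percent,
    mean_read_quality,
    merge,
    per_position_mean_quality,
    stats_of_record,
    yield_curve,
)

from .oracle import brute_force_channel_nucleotides, brute_force_read_type


def make_record(reads, run_id="run_a", channel=7, start=0.0, uncalled=False):
    return Fast5Record(
        source_key="x.fast5",
        tracking=TrackingInfo(run_id),
        channel=ChannelInfo(channel),
        read_start_time=start,
        reads={
            rt: BasecalledRead(rt, f"r_{rt}", seq, qual)
            for rt, (seq, qual) in reads.items()
        },
        uncalled=uncalled,
    )


@pytest.mark.parametrize(
    "seq,expected,all_n",
    [
        ("GGCC", 100.0, False),
        ("ATAT", 0.0, False),
        ("ACGTN", 50.0, False),  # N excluded: 2 of 4 called bases
        ("NNN", 0.0, True),
    ],
)
def test_gc_percent(seq, expected, all_n):
    gc, flag = gc_percent(seq)
    assert gc == pytest.approx(expected)
    assert flag is all_n


def test_gc_percent_rejects_empty():
    with pytest.raises(ValueError):
        gc_percent("")


@pytest.mark.parametrize(
    "qual,expected", [("!!!!", 0.0), ("IIII", 40.0), ("5?I", 30.0)]
)
def test_mean_read_quality(qual, expected):
    assert mean_read_quality(qual) == pytest.approx(expected)


def test_mean_read_quality_domain_errors():
    with pytest.raises(ValueError):
        mean_read_quality("")
    with pytest.raises(ValueError):
        mean_read_quality("I\x7fI")


def test_stats_of_record_single_read_bookkeeping():
    record = make_record({"template": ("ACGT", "IIII")}, channel=7)
    rs = stats_of_record(record)
    s = rs.runs["run_a"]["template"]
    assert s.n_reads == 1
    assert s.n_nucleotides == 4
    assert s.gc_histogram == {50: 1}
    assert s.reads_per_channel == {7: 1}
    assert s.quality_histogram == {40: 1}
    assert s.min_length == s.max_length == 4


def test_stats_of_record_two_types():
    record = make_record(
        {"template": ("ACGT", "IIII"), "2d": ("GGGG", "!!!!")}
    )
    rs = stats_of_record(record)
    assert set(rs.runs["run_a"]) == {"template", "2d"}


def test_uncalled_record_counts_only_in_uncalled_tally():
    record = make_record({}, uncalled=True)
    rs = stats_of_record(record)
    assert rs.uncalled_files == 1
    assert rs.runs == {}


def test_merge_identity_and_additivity():
    a = stats_of_record(make_record({"template": ("ACGT", "IIII")}))
    b = stats_of_record(make_record({"template": ("GG", "55")}, channel=3))
    assert merge(a, RunStats()).equals(a)
    ab = merge(a, b)
    assert ab.runs["run_a"]["template"].n_reads == 2
    assert ab.runs["run_a"]["template"].n_nucleotides == 6
    assert ab.equals(merge(b, a))


def test_fold_matches_brute_force_oracle(small_dataset):
    """Folding 50 single-record stats equals flat-list recomputation."""
    folder, manifest, cfg = small_dataset
    from poremap.pipeline import compute_stats

    result = compute_stats(folder, workers=1)
    report = finalize(result.result)
    per_type = report["runs"][cfg.run_id]
    for rt in per_type:
        expected = brute_force_read_type(manifest, rt)
        got = per_type[rt]
        for field in ("reads", "nucleotides", "min_length", "max_length",
                      "base_counts"):
            assert got[field] == expected[field], rt
        for field in ("mean_length", "gc_percent", "mean_quality"):
            assert got[field] == pytest.approx(expected[field], rel=1e-12), rt
        stats = result.result.runs[cfg.run_id][rt]
        assert dict(stats.nucleotides_per_channel) == (
            brute_force_channel_nucleotides(manifest, rt)
        )
        stats.check_invariants()


def test_finalize_examples():
    s = ReadTypeStats()
    s.add_read("A" * 10, "I" * 10, channel=1, start_time=0.0)
    s.add_read("C" * 30, "!" * 30, channel=2, start_time=5.0)
    out = finalize_read_type(s)
    assert out["mean_length"] == pytest.approx(20.0)
    assert out["min_length"] == 10
    assert out["max_length"] == 30
    # pooled A=10, C=30 -> %GC = 75
    assert out["gc_percent"] == pytest.approx(75.0)
    assert out["mean_quality"] == pytest.approx(20.0)


def test_finalize_handles_no_reads():
    assert finalize_read_type(ReadTypeStats()) == {"no_reads": True}
    report = finalize(RunStats())
    assert report["runs"] == {}


def test_pooled_gc_from_unit_base_counts():
    s = ReadTypeStats()
    s.add_read("ACGT", "IIII", channel=1, start_time=0.0)
    assert finalize_read_type(s)["gc_percent"] == pytest.approx(50.0)


def test_yield_curve_shape_and_conservation():
    s = ReadTypeStats()
    s.add_read("A" * 100, "I" * 100, channel=1, start_time=0.0)
    series = yield_curve(s, bin_width=60.0)
    assert series[-1][1] == 100
    s.add_read("C" * 50, "I" * 50, channel=1, start_time=125.0)
    series = yield_curve(s, bin_width=60.0)
    totals = [v for _, v in series]
    assert totals == sorted(totals)  # monotone cumulative
    assert totals[-1] == s.n_nucleotides
    assert yield_curve(ReadTypeStats()) == []


def test_per_position_mean_quality():
    s = ReadTypeStats()
    s.add_read("AC", "II", channel=1, start_time=0.0)
    assert per_position_mean_quality(s.position_profile) == [(0, 40.0), (1, 40.0)]
    t = ReadTypeStats()
    t.add_read("A", "I", channel=1, start_time=0.0)
    t.add_read("CC", "!!", channel=1, start_time=0.0)
    assert per_position_mean_quality(t.position_profile) == [(0, 20.0), (1, 0.0)]


def test_position_profile_conservation(small_dataset):
    folder, manifest, cfg = small_dataset
    from poremap.pipeline import compute_stats

    result = compute_stats(folder)
    for per_type in result.result.runs.values():
        for s in per_type.values():
            prof = s.position_profile
            base_sum = prof.base_counts.sum(axis=0)
            assert np.array_equal(base_sum, prof.obs_count)
            # every read covers position 0, so the profile peaks at n_reads
            assert prof.obs_count[0] == s.n_reads
            assert prof.obs_count.max() == s.n_reads


def test_quality_decay_slope_recovery(large_dataset):
    """The fitted per-position quality slope recovers the simulated decay."""
    folder, manifest, cfg = large_dataset
    from poremap.pipeline import compute_stats

    result = compute_stats(folder)
    s = result.result.runs[cfg.run_id]["template"]
    series = per_position_mean_quality(s.position_profile)
    counts = s.position_profile.obs_count
    pos = np.array([p for p, _ in series], dtype=float)
    q = np.array([v for _, v in series])
    w = counts[pos.astype(int)].astype(float)
    keep = w >= 30  # positions with decent coverage
    slope, slope_se = _wls_slope(pos[keep] / 1000.0, q[keep], w[keep], cfg.quality_sd)
    assert abs(slope - cfg.quality_slope) < 3 * slope_se


def _wls_slope(x, y, w, sd):
    """Weighted least squares slope and its standard error.

    Weights are observation counts; per-point variance is sd^2 / count.
    """
    W = w.sum()
    xbar = (w * x).sum() / W
    ybar = (w * y).sum() / W
    sxx = (w * (x - xbar) ** 2).sum()
    slope = (w * (x - xbar) * (y - ybar)).sum() / sxx
    se = sd / np.sqrt(sxx)
    return slope, se
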