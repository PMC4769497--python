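"""Per-run, per-read-type QC statistics as a mergeable map-reduce value.

The design follows the map-reduce contract: a *map* step turns one FAST5
record into a one-record :class:`RunStats`, and a *reduce* step merges any
two partial :class:`RunStats` values.  The merge is commutative and
associative with the empty ``RunStats`` as identity, so any partitioning of
the input over any number of workers finalizes to the same report.

Finalization produces every per-run summary quantity: read and nucleotide
counts, mean/min/max read length, nucleotide distribution (counts and
percentages), %GC, mean read quality, plus the histograms and per-position /
per-channel / yield-over-time profiles behind the QC plots.

Definitions (stated because upstream tools differ):

* mean read quality is the arithmetic mean of per-base Phred scores, and a
  run's mean quality is the mean over reads of per-read means;
* %GC is 100·(G+C)/(A+C+G+T) with N excluded from numerator and
  denominator; an all-N sequence reports 0 with a flag;
* histogram bins: read length in 500-nt bins, per-read GC in 101 integer
  percent bins, read quality in width-1 bins of the rounded per-read mean.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .fast5 import READ_TYPES, Fast5Record

__all__ = [
    "LENGTH_BIN_WIDTH",
    "MAX_PROFILE_POSITIONS",
    "PositionProfile",
    "ReadTypeStats",
    "RunStats",
    "gc_percent",
    "mean_read_quality",
    "stats_of_record",
    "merge",
    "finalize",
    "finalize_read_type",
    "yield_curve",
    "per_position_mean_quality",
]

BASES = ("A", "C", "G", "T", "N")
LENGTH_BIN_WIDTH = 500        # nt per read-length histogram bin
#: Per-position profiles are truncated here (overflow tallied) to bound
#: memory on pathological read lengths.
MAX_PROFILE_POSITIONS = 1_000_000

_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _BASE_INDEX[ord(_b)] = _i
    _BASE_INDEX[ord(_b.lower())] = _i


def gc_percent(sequence: str) -> tuple[float, bool]:
    """%GC of a nucleotide sequence; returns ``(percent, all_n_flag)``.

    N bases are excluded from both numerator and denominator.  A sequence
    consisting only of N has no defined GC content; it reports 0.0 with the
    flag set.
    """
    if not sequence:
        raise ValueError("gc_percent of empty sequence is undefined")
    counts = _base_counts(sequence)
    acgt = counts["A"] + counts["C"] + counts["G"] + counts["T"]
    if acgt == 0:
        return 0.0, True
    return 100.0 * (counts["G"] + counts["C"]) / acgt, False


def mean_read_quality(qualities: str) -> float:
    """Arithmetic mean Phred score of a Phred+33 quality string."""
    if not qualities:
        raise ValueError("mean quality of empty string is undefined")
    arr = np.frombuffer(qualities.encode("ascii"), dtype=np.uint8)
    if arr.min() < 33 or arr.max() > 126:
        raise ValueError("quality character outside Phred+33 range [33, 126]")
    return float(arr.mean()) - 33.0


def _base_counts(sequence: str) -> Counter:
    arr = _BASE_INDEX[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        bad = sequence[int(np.argmax(arr < 0))]
        raise ValueError(f"sequence contains non-ACGTN character {bad!r}")
    hist = np.bincount(arr, minlength=5)
    return Counter({b: int(hist[i]) for i, b in enumerate(BASES) if hist[i]})


@dataclass
class PositionProfile:
    """Per-position base counts and quality sums across reads.

    Invariant: at each position, the five base counts sum to the quality
    observation count, which equals the number of reads longer than that
    position (overflow beyond ``MAX_PROFILE_POSITIONS`` is tallied, not
    profiled).
    """

    base_counts: np.ndarray = field(
        default_factory=lambda: np.zeros((5, 0), dtype=np.int64)
    )
    quality_sum: np.ndarray = field(default_factory=lambda: np.zeros(0))
    obs_count: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    overflow_positions: int = 0

    def __len__(self) -> int:
        return self.quality_sum.shape[0]

    def _grow(self, n: int) -> None:
        old = len(self)
        if n <= old:
            return
        self.base_counts = np.pad(self.base_counts, ((0, 0), (0, n - old)))
        self.quality_sum = np.pad(self.quality_sum, (0, n - old))
        self.obs_count = np.pad(self.obs_count, (0, n - old))

    def add_read(self, sequence: str, qualities: str) -> None:
        n = len(sequence)
        if n > MAX_PROFILE_POSITIONS:
            self.overflow_positions += n - MAX_PROFILE_POSITIONS
            sequence = sequence[:MAX_PROFILE_POSITIONS]
            qualities = qualities[:MAX_PROFILE_POSITIONS]
            n = MAX_PROFILE_POSITIONS
        self._grow(n)
        base_idx = _BASE_INDEX[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
        phred = (
            np.frombuffer(qualities.encode("ascii"), dtype=np.uint8).astype(np.int64)
            - 33
        )
        np.add.at(self.base_counts, (base_idx, np.arange(n)), 1)
        self.quality_sum[:n] += phred
        self.obs_count[:n] += 1

    def merge(self, other: "PositionProfile") -> None:
        self._grow(len(other))
        m = len(other)
        self.base_counts[:, :m] += other.base_counts
        self.quality_sum[:m] += other.quality_sum
        self.obs_count[:m] += other.obs_count
        self.overflow_positions += other.overflow_positions

    def equals(self, other: "PositionProfile") -> bool:
        m = max(len(self), len(other))

        def pad2(a, n):
            return np.pad(a, ((0, 0), (0, n - a.shape[1])))

        return (
            np.array_equal(pad2(self.base_counts, m), pad2(other.base_counts, m))
            and np.array_equal(
                np.pad(self.quality_sum, (0, m - len(self))),
                np.pad(other.quality_sum, (0, m - len(other))),
            )
            and np.array_equal(
                np.pad(self.obs_count, (0, m - len(self))),
                np.pad(other.obs_count, (0, m - len(other))),
            )
            and self.overflow_positions == other.overflow_positions
        )


@dataclass
class ReadTypeStats:
    """Partial statistics for one read type; a commutative monoid under
    :meth:`merge_in` with the freshly-constructed value as identity."""

    n_reads: int = 0
    n_nucleotides: int = 0
    min_length: int | None = None
    max_length: int | None = None
    length_sum: int = 0
    base_counts: Counter = field(default_factory=Counter)
    length_histogram: Counter = field(default_factory=Counter)   # bin -> count
    gc_histogram: Counter = field(default_factory=Counter)       # int % -> count
    quality_histogram: Counter = field(default_factory=Counter)  # round(meanQ) -> count
    mean_quality_sum: float = 0.0
    all_n_reads: int = 0
    position_profile: PositionProfile = field(default_factory=PositionProfile)
    reads_per_channel: Counter = field(default_factory=Counter)
    nucleotides_per_channel: Counter = field(default_factory=Counter)
    yield_events: Counter = field(default_factory=Counter)  # (second, nt) -> count

    def add_read(
        self, sequence: str, qualities: str, channel: int, start_time: float
    ) -> None:
        n = len(sequence)
        if n == 0:
            raise ValueError("cannot accumulate an empty read")
        self.n_reads += 1
        self.n_nucleotides += n
        self.min_length = n if self.min_length is None else min(self.min_length, n)
        self.max_length = n if self.max_length is None else max(self.max_length, n)
        self.length_sum += n
        self.base_counts += _base_counts(sequence)
        self.length_histogram[n // LENGTH_BIN_WIDTH] += 1
        gc, all_n = gc_percent(sequence)
        if all_n:
            self.all_n_reads += 1
        self.gc_histogram[int(round(gc))] += 1
        mq = mean_read_quality(qualities)
        self.quality_histogram[int(round(mq))] += 1
        self.mean_quality_sum += mq
        self.position_profile.add_read(sequence, qualities)
        self.reads_per_channel[channel] += 1
        self.nucleotides_per_channel[channel] += n
        self.yield_events[(int(start_time), n)] += 1

    def merge_in(self, other: "ReadTypeStats") -> None:
        self.n_reads += other.n_reads
        self.n_nucleotides += other.n_nucleotides
        for attr, op in (("min_length", min), ("max_length", max)):
            a, b = getattr(self, attr), getattr(other, attr)
            setattr(self, attr, b if a is None else a if b is None else op(a, b))
        self.length_sum += other.length_sum
        self.base_counts += other.base_counts
        self.length_histogram += other.length_histogram
        self.gc_histogram += other.gc_histogram
        self.quality_histogram += other.quality_histogram
        self.mean_quality_sum += other.mean_quality_sum
        self.all_n_reads += other.all_n_reads
        self.position_profile.merge(other.position_profile)
        self.reads_per_channel += other.reads_per_channel
        self.nucleotides_per_channel += other.nucleotides_per_channel
        self.yield_events += other.yield_events

    def equals(self, other: "ReadTypeStats", *, float_rtol: float = 1e-9) -> bool:
        """Equality: exact on integer fields, relative tolerance on float sums."""
        ints_equal = (
            self.n_reads == other.n_reads
            and self.n_nucleotides == other.n_nucleotides
            and self.min_length == other.min_length
            and self.max_length == other.max_length
            and self.length_sum == other.length_sum
            and self.base_counts == other.base_counts
            and self.length_histogram == other.length_histogram
            and self.gc_histogram == other.gc_histogram
            and self.quality_histogram == other.quality_histogram
            and self.all_n_reads == other.all_n_reads
            and self.reads_per_channel == other.reads_per_channel
            and self.nucleotides_per_channel == other.nucleotides_per_channel
            and self.yield_events == other.yield_events
        )
        return (
            ints_equal
            and self.position_profile.equals(other.position_profile)
            and np.isclose(
                self.mean_quality_sum, other.mean_quality_sum, rtol=float_rtol, atol=0
            )
        )

    def check_invariants(self) -> None:
        """Raise AssertionError if the cross-sum conservation laws fail."""
        assert self.n_nucleotides == sum(self.base_counts.values())
        assert self.n_nucleotides == sum(
            nt * c for (_, nt), c in self.yield_events.items()
        )
        assert self.n_nucleotides == sum(self.nucleotides_per_channel.values())
        assert self.n_reads == sum(self.length_histogram.values())
        assert self.n_reads == sum(self.gc_histogram.values())
        assert self.n_reads == sum(self.quality_histogram.values())
        assert self.n_reads == sum(self.reads_per_channel.values())
        if self.n_reads > 0:
            assert self.min_length <= self.length_sum / self.n_reads <= self.max_length


@dataclass
class RunStats:
    """Map run_id -> read_type -> :class:`ReadTypeStats`; the reduce value.

    ``uncalled_files`` tallies FAST5 files carrying no basecalls at all;
    they are reported separately and never enter any read-type statistic.
    """

    runs: dict[str, dict[str, ReadTypeStats]] = field(default_factory=dict)
    uncalled_files: int = 0

    def get(self, run_id: str, read_type: str) -> ReadTypeStats:
        return self.runs.setdefault(run_id, {}).setdefault(read_type, ReadTypeStats())

    def merge_in(self, other: "RunStats") -> None:
        for run_id, per_type in other.runs.items():
            for read_type, rts in per_type.items():
                self.get(run_id, read_type).merge_in(rts)
        self.uncalled_files += other.uncalled_files

    def equals(self, other: "RunStats") -> bool:
        if self.uncalled_files != other.uncalled_files:
            return False
        if set(self.runs) != set(other.runs):
            return False
        for run_id in self.runs:
            if set(self.runs[run_id]) != set(other.runs[run_id]):
                return False
            for rt in self.runs[run_id]:
                if not self.runs[run_id][rt].equals(other.runs[run_id][rt]):
                    return False
        return True


def stats_of_record(record: Fast5Record) -> RunStats:
    """The map step: single-record statistics (every ``n_reads`` is 1)."""
    out = RunStats()
    if record.uncalled or not record.reads:
        out.uncalled_files += 1
        return out
    run_id = record.tracking.run_id
    for read_type, read in record.reads.items():
        out.get(run_id, read_type).add_read(
            read.sequence,
            read.qualities,
            record.channel.channel_number,
            record.read_start_time,
        )
    return out


def merge(a: RunStats, b: RunStats) -> RunStats:
    """The reduce step: component-wise monoid merge (non-destructive)."""
    out = RunStats()
    out.merge_in(a)
    out.merge_in(b)
    return out


def finalize_read_type(stats: ReadTypeStats) -> dict:
    """Summary numbers for one read type; ``{"no_reads": True}`` when empty."""
    if stats.n_reads == 0:
        return {"no_reads": True}
    pooled = stats.base_counts
    acgt = sum(pooled[b] for b in "ACGT")
    pooled_gc = 100.0 * (pooled["G"] + pooled["C"]) / acgt if acgt else 0.0
    return {
        "reads": stats.n_reads,
        "nucleotides": stats.n_nucleotides,
        "mean_length": stats.length_sum / stats.n_reads,
        "min_length": stats.min_length,
        "max_length": stats.max_length,
        "base_counts": {b: pooled.get(b, 0) for b in BASES},
        "base_percent": {
            b: 100.0 * pooled.get(b, 0) / stats.n_nucleotides for b in BASES
        },
        "gc_percent": pooled_gc,
        "gc_undefined": acgt == 0,
        "mean_quality": stats.mean_quality_sum / stats.n_reads,
    }


def finalize(stats: RunStats) -> dict:
    """Full report: run_id -> read_type -> summary dict, plus uncalled tally."""
    report = {
        "runs": {
            run_id: {
                rt: finalize_read_type(per_type[rt])
                for rt in READ_TYPES
                if rt in per_type
            }
            for run_id, per_type in sorted(stats.runs.items())
        },
        "uncalled_files": stats.uncalled_files,
    }
    return report


def yield_curve(
    stats: ReadTypeStats, bin_width: float = 60.0
) -> list[tuple[float, int]]:
    """Cumulative nucleotides over run time, binned at ``bin_width`` seconds.

    Times are relative to the experiment start.  The series is monotone
    non-decreasing and its final value equals ``n_nucleotides``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not stats.yield_events:
        return []
    per_bin: Counter = Counter()
    for (second, nt), count in stats.yield_events.items():
        per_bin[int(second // bin_width)] += nt * count
    series, total = [], 0
    for b in range(max(per_bin) + 1):
        total += per_bin.get(b, 0)
        series.append(((b + 1) * bin_width, total))
    return series


def per_position_mean_quality(profile: PositionProfile) -> list[tuple[int, float]]:
    """(position, mean Phred) at every position with >= 1 observation."""
    return [
        (p, float(profile.quality_sum[p] / profile.obs_count[p]))
        for p in range(len(profile))
        if profile.obs_count[p] > 0
    ]
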