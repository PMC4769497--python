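"""Wiring of the statistics job onto the map-reduce engine.

The map step parses one FAST5 blob and emits its single-record statistics;
the reduce step is the RunStats monoid merge.  Unparseable files surface as
per-key failures in the job result, never as crashes.
"""

from __future__ import annotations

import os
from typing import Iterable

from .engine import JobResult, JobSpec, run_job
from .extract import iter_source
from .fast5 import read_fast5
from .stats import RunStats, stats_of_record


def _map_stats(key: str, value: bytes) -> RunStats:
    record = read_fast5(value, load_events=False)
    record.source_key = key
    return stats_of_record(record)


def _merge_stats(a: RunStats, b: RunStats) -> RunStats:
    a.merge_in(b)
    return a


STATS_JOB = dict(map_fn=_map_stats, merge_fn=_merge_stats, identity=RunStats)


def compute_stats(
    source: str | os.PathLike | Iterable[tuple[str, bytes]],
    workers: int = 1,
    *,
    fail_fast: bool = False,
) -> JobResult:
    """Compute RunStats for a FAST5 folder, archive, or key-value stream."""
    pairs = (
        iter_source(source) if isinstance(source, (str, os.PathLike)) else source
    )
    job = JobSpec(workers=workers, **STATS_JOB)
    return run_job(pairs, job, fail_fast=fail_fast)
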