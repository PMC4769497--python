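"""Backend-agnostic execution of map/merge jobs over key-value sources.

A job is a map function from one ``(key, value)`` pair to a partial result
plus a merge function combining two partials; correctness of parallel
execution requires the merge to be associative and commutative with the
job's identity as neutral element (the test suite checks this by property
testing rather than assuming it).  Work is partitioned into contiguous key
ranges of the sorted source, so any worker count folds to the same result
as a sequential left fold — exactly for integer fields.

The single in-process pool here is one backend behind that contract; a
cluster adapter could plug into the same :class:`JobSpec` seam.
"""

from __future__ import annotations

import multiprocessing
import os
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Sequence

__all__ = ["KeyValuePair", "JobSpec", "JobResult", "MapFailure", "run_job"]

KeyValuePair = tuple[str, bytes]


class JobAbortedError(RuntimeError):
    """A map failure occurred while fail-fast was enabled, or merge raised."""


@dataclass(frozen=True)
class MapFailure:
    key: str
    error: str


@dataclass(frozen=True)
class JobSpec:
    """Map/merge contract of one job.

    ``identity`` is a factory (each call yields a fresh neutral element, so
    workers never share mutable state); ``merge_fn`` may mutate and return
    its first argument.
    """

    map_fn: Callable[[str, bytes], Any]
    merge_fn: Callable[[Any, Any], Any]
    identity: Callable[[], Any]
    workers: int = 1

    def __post_init__(self) -> None:
        if self.workers < 1:
            raise ValueError("workers must be >= 1")


@dataclass
class JobResult:
    result: Any
    pairs_seen: int = 0
    pairs_processed: int = 0
    failures: list[MapFailure] = field(default_factory=list)

    @property
    def pairs_failed(self) -> int:
        return len(self.failures)


def _fold_chunk(
    chunk: Sequence[KeyValuePair], job: JobSpec, fail_fast: bool
) -> JobResult:
    out = JobResult(result=job.identity())
    for key, value in chunk:
        out.pairs_seen += 1
        try:
            partial = job.map_fn(key, value)
        except Exception as exc:  # map failures are data errors, not bugs here
            if fail_fast:
                raise JobAbortedError(f"map failed for key {key!r}: {exc}") from exc
            out.failures.append(MapFailure(key, f"{type(exc).__name__}: {exc}"))
            continue
        out.result = job.merge_fn(out.result, partial)
        out.pairs_processed += 1
    return out


def _worker(args: tuple[Sequence[KeyValuePair], JobSpec, bool]) -> JobResult:
    return _fold_chunk(*args)


def partition_ranges(n: int, workers: int) -> list[tuple[int, int]]:
    """Split ``range(n)`` into at most ``workers`` contiguous near-equal ranges."""
    workers = max(1, min(workers, n)) if n else 1
    bounds = [round(i * n / workers) for i in range(workers + 1)]
    return [(a, b) for a, b in zip(bounds, bounds[1:]) if b > a]


def run_job(
    source: Iterable[KeyValuePair], job: JobSpec, *, fail_fast: bool = False
) -> JobResult:
    """Run ``job`` over ``source``; result equals the sequential left fold.

    Per-pair map failures are collected as ``(key, error)`` and reported in
    the result rather than aborting, unless ``fail_fast`` is set.  Progress
    accounting guarantees ``pairs_processed + pairs_failed == pairs_seen``.
    """
    pairs = source if isinstance(source, list) else list(source)
    if job.workers == 1 or len(pairs) <= 1:
        return _fold_chunk(pairs, job, fail_fast)

    ranges = partition_ranges(len(pairs), job.workers)
    ctx = multiprocessing.get_context(
        "fork" if os.name == "posix" else "spawn"
    )
    tasks = [(pairs[a:b], job, fail_fast) for a, b in ranges]
    try:
        with ctx.Pool(processes=len(ranges)) as pool:
            chunk_results = pool.map(_worker, tasks)
    except JobAbortedError:
        raise
    merged = JobResult(result=job.identity())
    for cr in chunk_results:  # chunk order == key order: deterministic fold
        try:
            merged.result = job.merge_fn(merged.result, cr.result)
        except Exception as exc:
            raise JobAbortedError(f"merge failed: {exc}") from exc
        merged.pairs_seen += cr.pairs_seen
        merged.pairs_processed += cr.pairs_processed
        merged.failures.extend(cr.failures)
    return merged
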