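"""FASTQ/FASTA extraction, event-table export and squiggle series.

Extraction writes, per run, exactly three sequence files — one per read
type (template, complement, 2D) — rather than one file per read, which is
what downstream mappers want.  FASTQ records are reproduced byte-identical
to the text embedded in each FAST5; FASTA is the 2-line projection
(header = read name, unwrapped sequence).  Files for absent read types are
created empty, and reads appear in source key order.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from .archive import Archive, is_archive
from .fast5 import READ_TYPES, Fast5Record, read_fast5

__all__ = [
    "SquigglePoint",
    "iter_source",
    "extract_fastq",
    "extract_fasta",
    "extract_events",
    "events_tsv",
    "squiggle_series",
]

#: Read-type token used in output file names (the field spells 2D upper-case).
FILE_TOKEN = {"template": "template", "complement": "complement", "2d": "2D"}


class NoEventsError(ValueError):
    """The requested read type carries no events table."""


@dataclass(frozen=True)
class SquigglePoint:
    time: float   # seconds from read start
    level: float  # signal mean, arbitrary current units


def iter_source(source: str | os.PathLike) -> Iterator[tuple[str, bytes]]:
    """Yield ``(key, fast5_bytes)`` from a FAST5 folder or an archive.

    Folders are walked recursively; keys are root-relative paths sorted
    byte-wise, matching archive key order, so both source kinds stream
    identically.
    """
    src = Path(source)
    if src.is_dir():
        for rel in sorted(
            p.relative_to(src).as_posix()
            for p in src.rglob("*")
            if p.is_file() and p.suffix.lower() == ".fast5"
        ):
            yield rel, (src / rel).read_bytes()
    elif is_archive(src):
        yield from Archive(src).scan()
    else:
        raise FileNotFoundError(f"{source} is neither a FAST5 folder nor an archive")


def _extract_sequences(
    source: str | os.PathLike | Iterable[tuple[str, bytes]],
    out_dir: str | os.PathLike,
    suffix: str,
    render,
) -> dict[str, dict[str, int]]:
    out_root = Path(out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    if not os.access(out_root, os.W_OK):
        raise OSError(f"output directory {out_root} is not writable")
    pairs = (
        iter_source(source)
        if isinstance(source, (str, os.PathLike))
        else iter(source)
    )
    handles: dict[tuple[str, str], object] = {}
    counts: dict[str, dict[str, int]] = {}

    def handle(run_id: str, rt: str):
        hkey = (run_id, rt)
        if hkey not in handles:
            run_dir = out_root / run_id
            run_dir.mkdir(parents=True, exist_ok=True)
            # create all three per-type files up front so absent types
            # still yield (empty) files
            for other in READ_TYPES:
                path = run_dir / f"{FILE_TOKEN[other]}{suffix}"
                if (run_id, other) not in handles:
                    handles[(run_id, other)] = open(path, "w")
                    counts.setdefault(run_id, {})[other] = 0
        return handles[hkey]

    try:
        for key, blob in pairs:
            record = read_fast5(blob)
            record = _rekey(record, key)
            run_id = record.tracking.run_id
            if not record.reads:
                handle(run_id, "template")  # materialize the run's files
                continue
            for rt, read in record.reads.items():
                fh = handle(run_id, rt)
                fh.write(render(read))
                counts[run_id][rt] += 1
    finally:
        for fh in handles.values():
            fh.close()
    return counts


def _rekey(record: Fast5Record, key: str) -> Fast5Record:
    record.source_key = key
    return record


def _fastq_text(read) -> str:
    text = read.fastq_text
    return text if text.endswith("\n") else text + "\n"


def _fasta_text(read) -> str:
    return f">{read.read_name}\n{read.sequence}\n"


def extract_fastq(source, out_dir) -> dict[str, dict[str, int]]:
    """Write per-run ``template/complement/2D.fastq``; returns counts per type.

    Each record's text is byte-identical to the FASTQ embedded in its FAST5.
    """
    return _extract_sequences(source, out_dir, ".fastq", _fastq_text)


def extract_fasta(source, out_dir) -> dict[str, dict[str, int]]:
    """Write per-run ``template/complement/2D.fasta`` (2-line records)."""
    return _extract_sequences(source, out_dir, ".fasta", _fasta_text)


def events_tsv(record: Fast5Record, read_type: str) -> str:
    """Tab-separated event table (mean, stdv, start, length, model_state, move).

    Floats are printed with 6 significant digits.
    """
    if read_type not in record.events or not record.events[read_type]:
        raise NoEventsError(
            f"{record.source_key}: no events stored for read type {read_type!r}"
        )
    lines = ["mean\tstdv\tstart\tlength\tmodel_state\tmove"]
    for e in record.events[read_type]:
        lines.append(
            f"{e.mean:.6g}\t{e.stdv:.6g}\t{e.start:.6g}\t{e.length:.6g}"
            f"\t{e.model_state}\t{e.move}"
        )
    return "\n".join(lines) + "\n"


def extract_events(
    source: str | os.PathLike, read_key: str, read_type: str
) -> str:
    """Event table for one read (by source key) as TSV text."""
    src = Path(source)
    if src.is_dir():
        path = src / read_key
        if not path.is_file():
            raise KeyError(f"read key {read_key!r} not found under {source}")
        record = read_fast5(path.read_bytes())
    else:
        record = read_fast5(Archive(src).lookup(read_key))  # KeyNotFoundError if absent
    record.source_key = read_key
    return events_tsv(record, read_type)


def squiggle_series(record: Fast5Record, read_type: str) -> list[SquigglePoint]:
    """Step-function signal trace: two points (start and end) per event.

    This is the series behind the classic squiggle plot of pore current
    level over time; times are non-decreasing and the point count is twice
    the event count.
    """
    if read_type not in record.events or not record.events[read_type]:
        raise NoEventsError(
            f"{record.source_key}: no events stored for read type {read_type!r}"
        )
    points: list[SquigglePoint] = []
    for e in record.events[read_type]:
        points.append(SquigglePoint(e.start, e.mean))
        points.append(SquigglePoint(e.start + e.length, e.mean))
    return points
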