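"""Reader/writer and data model for the classic single-read FAST5 dialect.

A FAST5 file is an HDF5 container holding one nanopore read: basecalled
sequences embedded as FASTQ text, event tables (the segmented pore-current
signal), and channel/run metadata.  One file can carry a template read, a
complement read and/or a 2D read (the basecaller's combination of both
strands), in any combination.

This module implements the 2014-2016 single-read layout:

* basecalls under ``/Analyses/Basecall_2D_<NNN>/BaseCalled_{template,complement,2D}``
  with a ``Fastq`` string dataset and an ``Events`` compound dataset;
* channel attributes under ``/UniqueGlobalKey/channel_id``;
* run metadata under ``/UniqueGlobalKey/tracking_id``;
* the read start time as a ``start_time`` attribute (in samples) on an
  event-detection read group, falling back to the first event's start.

Multi-read FAST5 (post-2017) and POD5 are out of scope.
"""

from __future__ import annotations

import io
import os
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "READ_TYPES",
    "EventRecord",
    "BasecalledRead",
    "ChannelInfo",
    "TrackingInfo",
    "Fast5Record",
    "Fast5FormatError",
    "UncalledFileError",
    "read_fast5",
    "write_fast5",
    "list_read_types",
    "parse_fastq_text",
]

#: Canonical read-type tokens, in reporting order.
READ_TYPES = ("template", "complement", "2d")

# HDF5 group-name component per read type (the on-disk dialect spells 2D
# upper-case).
_HDF5_TYPE_NAME = {"template": "template", "complement": "complement", "2d": "2D"}
_TYPE_FROM_HDF5 = {v: k for k, v in _HDF5_TYPE_NAME.items()}


class Fast5FormatError(ValueError):
    """The input is not a well-formed FAST5/HDF5 container."""


class UncalledFileError(ValueError):
    """Valid HDF5, but no recognized basecall group and no raw section."""


@dataclass(frozen=True)
class EventRecord:
    """One translocation event: a segment of the pore current signal."""

    mean: float          # signal level, arbitrary current units
    stdv: float          # signal spread, >= 0
    start: float         # seconds from read start; non-decreasing in a table
    length: float        # event duration in seconds, >= 0
    model_state: str     # k-mer label over {A,C,G,T}
    move: int            # basecaller step, >= 0

    def __post_init__(self) -> None:
        if self.stdv < 0 or self.length < 0:
            raise ValueError("event stdv and length must be non-negative")
        if self.move < 0:
            raise ValueError("event move must be non-negative")
        if not self.model_state:
            raise ValueError("event model_state must be non-empty")


@dataclass(frozen=True)
class BasecalledRead:
    """One basecalled sequence (template, complement or 2D) with qualities.

    ``fastq_text`` preserves the exact FASTQ text embedded in the FAST5 so
    extraction can reproduce it byte-for-byte; the parsed fields are derived
    from it.
    """

    read_type: str
    read_name: str
    sequence: str
    qualities: str       # Phred+33 ASCII
    fastq_text: str = ""

    def __post_init__(self) -> None:
        if self.read_type not in READ_TYPES:
            raise ValueError(f"unknown read type {self.read_type!r}")
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and qualities must have equal length")
        for ch in self.qualities:
            if not 33 <= ord(ch) <= 126:
                raise ValueError(f"quality character {ch!r} outside Phred+33 range")
        if not self.fastq_text:
            object.__setattr__(
                self,
                "fastq_text",
                f"@{self.read_name}\n{self.sequence}\n+\n{self.qualities}\n",
            )


@dataclass(frozen=True)
class ChannelInfo:
    """Identity and sampling rate of the flowcell channel (pore)."""

    channel_number: int
    sampling_rate: float = 5000.0

    def __post_init__(self) -> None:
        if self.channel_number < 1:
            raise ValueError("channel_number must be >= 1")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")


@dataclass(frozen=True)
class TrackingInfo:
    """Run-level metadata; ``run_id`` groups all per-run outputs."""

    run_id: str
    exp_start_time: int = 0
    flow_cell_id: str = ""
    device_id: str = ""

    def __post_init__(self) -> None:
        if not self.run_id:
            raise ValueError("run_id must be non-empty")


@dataclass
class Fast5Record:
    """One sequencer read: metadata plus up to three basecalled reads.

    ``reads`` and ``events`` are partial maps keyed by read type.  A record
    with no basecalls at all is flagged ``uncalled`` (raw signal was captured
    but the basecaller produced nothing usable).
    """

    source_key: str
    tracking: TrackingInfo
    channel: ChannelInfo
    read_start_time: float = 0.0
    reads: dict[str, BasecalledRead] = field(default_factory=dict)
    events: dict[str, list[EventRecord]] = field(default_factory=dict)
    uncalled: bool = False

    def validate(self) -> None:
        if self.read_start_time < 0:
            raise ValueError("read_start_time must be >= 0")
        if not self.reads and not self.uncalled:
            raise ValueError("record without basecalls must be flagged uncalled")
        if "2d" in self.reads and "template" not in self.reads:
            # 2D is a combination of both strands, so template should exist;
            # accept anyway (be liberal in what we accept).
            warnings.warn(
                f"{self.source_key}: 2D read present without a template read",
                stacklevel=2,
            )
        for rt, read in self.reads.items():
            if read.read_type != rt:
                raise ValueError(f"read stored under {rt!r} has type {read.read_type!r}")
        for rt, evs in self.events.items():
            starts = [e.start for e in evs]
            if any(b < a for a, b in zip(starts, starts[1:])):
                raise ValueError(f"{rt} events have decreasing start times")


def list_read_types(record: Fast5Record) -> set[str]:
    """Read types (template/complement/2d) basecalled in this record."""
    return set(record.reads)


def parse_fastq_text(text: str) -> tuple[str, str, str]:
    """Split one 4-line FASTQ record into (read_name, sequence, qualities)."""
    lines = text.splitlines()
    if len(lines) < 4 or not lines[0].startswith("@") or not lines[2].startswith("+"):
        raise Fast5FormatError("embedded FASTQ is not a 4-line record")
    name = lines[0][1:].split()[0] if len(lines[0]) > 1 else ""
    return name, lines[1], lines[3]


_EVENT_FIELDS = ("mean", "stdv", "start", "length", "model_state", "move")


def _events_dtype(k: int) -> np.dtype:
    return np.dtype(
        [
            ("mean", "<f8"),
            ("stdv", "<f8"),
            ("start", "<f8"),
            ("length", "<f8"),
            ("model_state", f"S{max(k, 1)}"),
            ("move", "<i8"),
        ]
    )


def _decode(value) -> str:
    if isinstance(value, bytes):
        return value.decode("utf-8", "replace")
    return str(value)


def _parse_events(dataset: h5py.Dataset) -> list[EventRecord]:
    table = dataset[()]
    names = table.dtype.names or ()
    missing = [f for f in _EVENT_FIELDS if f not in names]
    if missing:
        raise Fast5FormatError(f"events table lacks fields {missing}")
    return [
        EventRecord(
            mean=float(row["mean"]),
            stdv=float(row["stdv"]),
            start=float(row["start"]),
            length=float(row["length"]),
            model_state=_decode(row["model_state"]),
            move=int(row["move"]),
        )
        for row in table
    ]


def _select_basecall_group(analyses: h5py.Group, override: str | None) -> h5py.Group | None:
    """Pick the basecall group: explicit override, else highest-indexed.

    Files re-basecalled with newer models accumulate Basecall_* groups; the
    highest numeric suffix is taken as the most recent.
    """
    if override is not None:
        if override not in analyses:
            raise Fast5FormatError(f"requested analysis group {override!r} not present")
        return analyses[override]
    best_name, best_idx = None, -1
    for name in analyses:
        if not name.startswith("Basecall_"):
            continue
        suffix = name.rsplit("_", 1)[-1]
        idx = int(suffix) if suffix.isdigit() else 0
        if idx > best_idx or (idx == best_idx and (best_name or "") < name):
            best_name, best_idx = name, idx
    return analyses[best_name] if best_name is not None else None


def read_fast5(
    content: str | os.PathLike | bytes,
    *,
    analysis_group: str | None = None,
    load_events: bool = True,
) -> Fast5Record:
    """Parse one FAST5 file (path or raw bytes) into a :class:`Fast5Record`.

    Absent sections yield absent map entries, never invented defaults; a file
    with metadata but no basecalls comes back flagged ``uncalled``.
    ``load_events=False`` skips decoding event tables (they are large and
    sequence-level statistics never touch them).

    Raises
    ------
    Fast5FormatError
        The content is not a well-formed HDF5/FAST5 container.
    UncalledFileError
        Valid HDF5 with neither a recognized analysis group nor a raw /
        event-detection section.
    """
    if isinstance(content, (bytes, bytearray, memoryview)):
        source, key = io.BytesIO(bytes(content)), "<bytes>"
    else:
        source, key = os.fspath(content), os.path.basename(os.fspath(content))
    try:
        handle = h5py.File(source, "r")
    except (OSError, ValueError) as exc:
        raise Fast5FormatError(f"{key}: not a readable HDF5 container ({exc})") from None
    with handle as f:
        try:
            return _parse_open_file(f, key, analysis_group, load_events)
        except (Fast5FormatError, UncalledFileError):
            raise
        except Exception as exc:
            # truncated/corrupted containers can fail anywhere inside the
            # HDF5 library; totality demands a single declared error class
            raise Fast5FormatError(f"{key}: corrupt FAST5 content ({exc})") from exc


def _parse_open_file(
    f: h5py.File, key: str, analysis_group: str | None, load_events: bool = True
) -> Fast5Record:
    # --- metadata -------------------------------------------------------
    run_id, exp_start, flow_cell, device = "unknown_run", 0, "", ""
    if "UniqueGlobalKey/tracking_id" in f:
        attrs = f["UniqueGlobalKey/tracking_id"].attrs
        run_id = _decode(attrs.get("run_id", run_id)) or "unknown_run"
        exp_start = int(attrs.get("exp_start_time", 0))
        flow_cell = _decode(attrs.get("flow_cell_id", ""))
        device = _decode(attrs.get("device_id", ""))
    tracking = TrackingInfo(run_id, exp_start, flow_cell, device)

    channel_number, sampling_rate = 1, 5000.0
    if "UniqueGlobalKey/channel_id" in f:
        attrs = f["UniqueGlobalKey/channel_id"].attrs
        channel_number = int(attrs.get("channel_number", 1))
        sampling_rate = float(attrs.get("sampling_rate", 5000.0))
    channel = ChannelInfo(channel_number, sampling_rate)

    # --- basecalls ------------------------------------------------------
    reads: dict[str, BasecalledRead] = {}
    events: dict[str, list[EventRecord]] = {}
    basecall = None
    if "Analyses" in f:
        basecall = _select_basecall_group(f["Analyses"], analysis_group)
    if basecall is not None:
        for rt, hdf5_name in _HDF5_TYPE_NAME.items():
            group_name = f"BaseCalled_{hdf5_name}"
            if group_name not in basecall:
                continue
            section = basecall[group_name]
            if "Fastq" in section:
                text = _decode(section["Fastq"][()])
                name, seq, qual = parse_fastq_text(text)
                try:
                    reads[rt] = BasecalledRead(rt, name, seq, qual, fastq_text=text)
                except ValueError as exc:
                    raise Fast5FormatError(f"{key}: bad {rt} FASTQ ({exc})") from None
            if "Events" in section and load_events:
                events[rt] = _parse_events(section["Events"])

    has_raw = any(g in f for g in ("Raw", "Analyses/EventDetection_000"))
    if not reads and not events and not has_raw and basecall is None:
        raise UncalledFileError(
            f"{key}: no recognized basecall analysis group and no raw section"
        )

    # --- read start time ------------------------------------------------
    read_start = _read_start_time(f, sampling_rate, events)

    record = Fast5Record(
        source_key=key,
        tracking=tracking,
        channel=channel,
        read_start_time=read_start,
        reads=reads,
        events=events,
        uncalled=not reads,
    )
    record.validate()
    return record


def _read_start_time(
    f: h5py.File, sampling_rate: float, events: dict[str, list[EventRecord]]
) -> float:
    # Preferred source: start_time attribute (in samples) on the
    # event-detection read group; fallback: first event's start.
    if "Analyses" in f:
        for name in sorted(f["Analyses"], reverse=True):
            if not name.startswith("EventDetection_"):
                continue
            reads_group = f["Analyses"][name].get("Reads")
            if reads_group is None:
                continue
            for read_name in reads_group:
                attrs = reads_group[read_name].attrs
                if "start_time" in attrs:
                    return float(attrs["start_time"]) / sampling_rate
    for rt in READ_TYPES:
        if events.get(rt):
            return events[rt][0].start
    return 0.0


def write_fast5(record: Fast5Record, destination: str | os.PathLike) -> int:
    """Write ``record`` in the single-read FAST5 dialect; returns bytes written.

    The file is fully reproducible: identical records yield identical bytes
    (HDF5 timestamp tracking is disabled).  ``read_fast5`` on the result
    reproduces the record field-for-field.
    """
    record.validate()  # fail before any write
    dest = os.fspath(destination)
    str_dtype = h5py.string_dtype(encoding="utf-8")
    with h5py.File(dest, "w") as f:
        t = f.create_group("UniqueGlobalKey/tracking_id")
        t.attrs["run_id"] = record.tracking.run_id
        t.attrs["exp_start_time"] = record.tracking.exp_start_time
        t.attrs["flow_cell_id"] = record.tracking.flow_cell_id
        t.attrs["device_id"] = record.tracking.device_id
        c = f.create_group("UniqueGlobalKey/channel_id")
        c.attrs["channel_number"] = record.channel.channel_number
        c.attrs["sampling_rate"] = record.channel.sampling_rate

        ed = f.create_group("Analyses/EventDetection_000/Reads/Read_0")
        ed.attrs["start_time"] = int(
            round(record.read_start_time * record.channel.sampling_rate)
        )

        if record.reads or record.events:
            bc = f.create_group("Analyses/Basecall_2D_000")
            for rt in READ_TYPES:
                if rt not in record.reads and rt not in record.events:
                    continue
                section = bc.create_group(f"BaseCalled_{_HDF5_TYPE_NAME[rt]}")
                if rt in record.reads:
                    section.create_dataset(
                        "Fastq",
                        data=record.reads[rt].fastq_text,
                        dtype=str_dtype,
                        track_times=False,
                    )
                if rt in record.events:
                    evs = record.events[rt]
                    k = max((len(e.model_state) for e in evs), default=1)
                    table = np.zeros(len(evs), dtype=_events_dtype(k))
                    for i, e in enumerate(evs):
                        table[i] = (
                            e.mean,
                            e.stdv,
                            e.start,
                            e.length,
                            e.model_state.encode(),
                            e.move,
                        )
                    section.create_dataset("Events", data=table, track_times=False)
    return os.path.getsize(dest)
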