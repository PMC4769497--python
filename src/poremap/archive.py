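"""Sorted, indexed, optionally compressed key-value archive of FAST5 files.

A portable stand-in for a sorted sequence file with a companion lookup
index: the FAST5 filename is the key and the file content is the value.
Two files make up an archive:

* ``<name>.data`` — magic ``NPKV``, u16 version, u8 codec, then records,
  each ``u32 key_len | key bytes | u64 raw_len | u64 stored_len | value``;
* ``<name>.index`` — magic ``NPKI``, u16 version, u64 record_count, then
  sorted entries ``u32 key_len | key bytes | u64 offset | u64 stored_len |
  u64 raw_len``.

All integers are little-endian and unsigned.  Keys are paths relative to
the import root (so identical basenames in different subfolders stay
unique), sorted byte-wise; offsets point at the start of each data record.
Compression (deflate) is per-record, preserving random access by key.
Archives are write-once.
"""

from __future__ import annotations

import bisect
import logging
import os
import struct
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

__all__ = [
    "ArchiveError",
    "KeyNotFoundError",
    "ArchiveIndexEntry",
    "ImportSummary",
    "Archive",
    "import_folder",
    "is_archive",
    "resolve_archive_base",
]

log = logging.getLogger(__name__)

DATA_MAGIC = b"NPKV"
INDEX_MAGIC = b"NPKI"
FORMAT_VERSION = 1
CODEC_NONE = 0
CODEC_DEFLATE = 1

_U16 = struct.Struct("<H")
_U32 = struct.Struct("<I")
_U64 = struct.Struct("<Q")
_LENS = struct.Struct("<QQ")  # raw_len, stored_len


class ArchiveError(ValueError):
    """The archive files are malformed or inconsistent."""


class KeyNotFoundError(KeyError):
    """Lookup key absent from the archive index."""


@dataclass(frozen=True)
class ArchiveIndexEntry:
    key: str
    offset: int        # byte position of the record in the data file
    stored_length: int # bytes on disk (after compression)
    raw_length: int    # bytes after decompression


@dataclass(frozen=True)
class ImportSummary:
    files_imported: int
    input_bytes: int
    stored_bytes: int
    files_skipped: int = 0


def resolve_archive_base(path: str | os.PathLike) -> Path:
    """Map a user-supplied archive path to the base (no ``.data``/``.index``)."""
    p = Path(path)
    if p.suffix in (".data", ".index"):
        return p.with_suffix("")
    return p


def is_archive(path: str | os.PathLike) -> bool:
    """True if ``path`` names an archive (checked by data-file magic)."""
    base = resolve_archive_base(path)
    data = base.with_suffix(base.suffix + ".data")
    try:
        with open(data, "rb") as fh:
            return fh.read(4) == DATA_MAGIC
    except OSError:
        return False


def import_folder(
    source_folder: str | os.PathLike,
    archive: str | os.PathLike,
    compress: bool = False,
) -> ImportSummary:
    """Import every ``*.fast5`` under ``source_folder`` into a new archive.

    Files are enumerated recursively; keys are root-relative paths with
    ``/`` separators, stored in sorted order.  Non-FAST5 files are skipped
    with a logged count; unreadable files are logged and skipped without
    aborting the import.
    """
    root = Path(source_folder)
    if not root.is_dir():
        raise ArchiveError(f"source folder {root} does not exist")
    paths = sorted(
        p.relative_to(root).as_posix()
        for p in root.rglob("*")
        if p.is_file() and p.suffix.lower() == ".fast5"
    )
    non_fast5 = sum(1 for p in root.rglob("*") if p.is_file()) - len(paths)
    if non_fast5:
        log.info("skipping %d non-FAST5 files in %s", non_fast5, root)
    if not paths:
        log.warning("no FAST5 files found in %s; writing empty archive", root)

    base = resolve_archive_base(archive)
    base.parent.mkdir(parents=True, exist_ok=True)
    codec = CODEC_DEFLATE if compress else CODEC_NONE
    entries: list[ArchiveIndexEntry] = []
    imported = skipped = input_bytes = 0

    with open(base.with_suffix(base.suffix + ".data"), "wb") as data:
        data.write(DATA_MAGIC + _U16.pack(FORMAT_VERSION) + bytes([codec]))
        for key in paths:
            try:
                raw = (root / key).read_bytes()
            except OSError as exc:
                log.error("cannot read %s: %s; skipping", key, exc)
                skipped += 1
                continue
            stored = zlib.compress(raw, 6) if compress else raw
            offset = data.tell()
            kb = key.encode("utf-8")
            data.write(_U32.pack(len(kb)) + kb)
            data.write(_LENS.pack(len(raw), len(stored)))
            data.write(stored)
            entries.append(ArchiveIndexEntry(key, offset, len(stored), len(raw)))
            imported += 1
            input_bytes += len(raw)

    with open(base.with_suffix(base.suffix + ".index"), "wb") as index:
        index.write(INDEX_MAGIC + _U16.pack(FORMAT_VERSION))
        index.write(_U64.pack(len(entries)))
        for e in entries:
            kb = e.key.encode("utf-8")
            index.write(_U32.pack(len(kb)) + kb)
            index.write(_U64.pack(e.offset))
            index.write(_U64.pack(e.stored_length))
            index.write(_U64.pack(e.raw_length))

    stored_bytes = sum(e.stored_length for e in entries)
    return ImportSummary(imported, input_bytes, stored_bytes, skipped)


class Archive:
    """Read-side handle: key lookup by binary search and ordered scans."""

    def __init__(self, path: str | os.PathLike):
        self.base = resolve_archive_base(path)
        self.data_path = self.base.with_suffix(self.base.suffix + ".data")
        self.index_path = self.base.with_suffix(self.base.suffix + ".index")
        self.codec = self._read_data_header()
        self.entries = self._read_index()
        self._keys = [e.key for e in self.entries]

    def _read_data_header(self) -> int:
        try:
            with open(self.data_path, "rb") as fh:
                header = fh.read(7)
        except OSError as exc:
            raise ArchiveError(f"cannot open archive data file: {exc}") from None
        if len(header) < 7 or header[:4] != DATA_MAGIC:
            raise ArchiveError(f"{self.data_path}: bad data-file magic")
        (version,) = _U16.unpack(header[4:6])
        if version != FORMAT_VERSION:
            raise ArchiveError(f"unsupported archive version {version}")
        codec = header[6]
        if codec not in (CODEC_NONE, CODEC_DEFLATE):
            raise ArchiveError(f"unknown codec id {codec}")
        return codec

    def _read_index(self) -> list[ArchiveIndexEntry]:
        try:
            blob = self.index_path.read_bytes()
        except OSError as exc:
            raise ArchiveError(f"cannot open archive index: {exc}") from None
        if blob[:4] != INDEX_MAGIC:
            raise ArchiveError(f"{self.index_path}: bad index magic")
        (count,) = _U64.unpack_from(blob, 6)
        pos = 14
        entries: list[ArchiveIndexEntry] = []
        prev_key: bytes | None = None
        prev_off = -1
        for _ in range(count):
            (klen,) = _U32.unpack_from(blob, pos)
            pos += 4
            kb = blob[pos : pos + klen]
            pos += klen
            offset, stored, raw = struct.unpack_from("<QQQ", blob, pos)
            pos += 24
            if prev_key is not None and kb <= prev_key:
                raise ArchiveError("index keys not strictly ascending")
            if offset <= prev_off:
                raise ArchiveError("index offsets not strictly increasing")
            prev_key, prev_off = kb, offset
            entries.append(ArchiveIndexEntry(kb.decode("utf-8"), offset, stored, raw))
        return entries

    def __len__(self) -> int:
        return len(self.entries)

    def keys(self) -> list[str]:
        return list(self._keys)

    def _decode_value(self, stored: bytes, raw_len: int, key: str) -> bytes:
        if self.codec == CODEC_DEFLATE:
            try:
                value = zlib.decompress(stored)
            except zlib.error as exc:
                raise ArchiveError(f"record {key!r}: corrupt payload ({exc})") from None
        else:
            value = stored
        if len(value) != raw_len:
            raise ArchiveError(
                f"record {key!r}: raw length {len(value)} != indexed {raw_len}"
            )
        return value

    def lookup(self, key: str) -> bytes:
        """Return the exact original file bytes stored under ``key``.

        Binary search over the sorted index: at most ceil(log2 n)+1 probes.
        """
        i = bisect.bisect_left(self._keys, key)
        if i == len(self._keys) or self._keys[i] != key:
            raise KeyNotFoundError(key)
        entry = self.entries[i]
        with open(self.data_path, "rb") as fh:
            fh.seek(entry.offset)
            (klen,) = _U32.unpack(fh.read(4))
            fh.seek(klen, os.SEEK_CUR)
            raw_len, stored_len = _LENS.unpack(fh.read(16))
            if (raw_len, stored_len) != (entry.raw_length, entry.stored_length):
                raise ArchiveError(f"record {key!r}: data/index length mismatch")
            stored = fh.read(stored_len)
        if len(stored) != stored_len:
            raise ArchiveError(f"record {key!r}: truncated data file")
        return self._decode_value(stored, raw_len, key)

    def scan(self, start: int = 0, stop: int | None = None) -> Iterator[tuple[str, bytes]]:
        """Yield ``(key, value)`` pairs in ascending key order.

        ``start``/``stop`` are index positions, so a scan can be restarted
        from any point — this is what lets workers partition an archive
        into contiguous key ranges.
        """
        stop = len(self.entries) if stop is None else stop
        if not 0 <= start <= stop <= len(self.entries):
            raise IndexError("scan range out of bounds")
        with open(self.data_path, "rb") as fh:
            for entry in self.entries[start:stop]:
                fh.seek(entry.offset)
                (klen,) = _U32.unpack(fh.read(4))
                key = fh.read(klen).decode("utf-8")
                if key != entry.key:
                    raise ArchiveError(
                        f"data/index key mismatch at offset {entry.offset}"
                    )
                raw_len, stored_len = _LENS.unpack(fh.read(16))
                stored = fh.read(stored_len)
                if len(stored) != stored_len:
                    raise ArchiveError(f"record {entry.key!r}: truncated data file")
                yield key, self._decode_value(stored, raw_len, entry.key)
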