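"""On-disk layout of the qname index files.

Both index files share one fixed-size-prefix record layout::

    1 byte   length of qname (N), 1..254
    N bytes  qname (key)
    8 bytes  virtual offset (pointer), little-endian

and both are plain BGZF streams terminated by the standard BGZF EOF block,
so generic gzip tooling can decompress them.  In the data file the pointer
is a virtual offset into the BAM; in the top index it is a virtual offset
into the data file.  Entries are written in sorted order: bytewise
lexicographic on the raw qname, ties broken by ascending pointer, so that
readers and writers agree on a locale-independent total order.
"""

from __future__ import annotations

import os
import struct
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Optional, Tuple

from Bio import bgzf

from .bam_io import VirtualOffset

#: SAM caps QNAME at 254 characters.
MAX_QNAME_LEN = 254

#: Directory created beside the BAM, and the two files inside it.
INDEX_DIR_SUFFIX = ".atlantool-index"
DATA_FILE_NAME = "qname.v3.data.bgz"
TOP_FILE_NAME = "qname.v3.index.bgz"

#: Flush the BGZF writer once this many uncompressed bytes are buffered.
#: Fixed so that identical entry streams produce identical compressed bytes.
BLOCK_FLUSH_THRESHOLD = 60_000

_POINTER = struct.Struct("<Q")


class IndexFormatError(Exception):
    """An entry violates the on-disk layout constraints."""


class IndexCorruptionError(Exception):
    """An index file does not decode cleanly; it should be rebuilt."""


class IndexEntry(NamedTuple):
    """One (qname, pointer) pair — the atom of both index files."""

    qname: bytes
    pointer: VirtualOffset

    @property
    def sort_key(self) -> Tuple[bytes, int]:
        return (self.qname, self.pointer.packed)


class IndexPair(NamedTuple):
    """The two on-disk index artifacts for one BAM."""

    directory: Path
    data_path: Path
    top_path: Path

    @classmethod
    def locate(
        cls, bam_path: str | os.PathLike, index_dir: str | os.PathLike | None = None
    ) -> "IndexPair":
        directory = Path(index_dir) if index_dir else Path(
            os.fspath(bam_path) + INDEX_DIR_SUFFIX
        )
        return cls(directory, directory / DATA_FILE_NAME, directory / TOP_FILE_NAME)

    def exists(self) -> bool:
        return self.data_path.is_file() and self.top_path.is_file()


def encode_entry(entry: IndexEntry) -> bytes:
    """Serialize an entry as ``[N][qname bytes][8-byte LE pointer]``."""
    n = len(entry.qname)
    if not 1 <= n <= MAX_QNAME_LEN:
        raise IndexFormatError(
            f"qname length must be 1..{MAX_QNAME_LEN}, got {n} ({entry.qname[:40]!r})"
        )
    return bytes([n]) + entry.qname + _POINTER.pack(entry.pointer.packed)


def decode_entry(stream) -> Optional[IndexEntry]:
    """Read one entry from a byte stream; ``None`` at clean end-of-stream.

    Consumes exactly ``1 + N + 8`` bytes.  A stream ending mid-entry raises
    :class:`IndexCorruptionError` naming the byte position.
    """
    pos = stream.tell()
    head = stream.read(1)
    if not head:
        return None
    n = head[0]
    if n == 0:
        raise IndexCorruptionError(f"zero-length qname at stream position {pos}")
    body = stream.read(n + 8)
    if len(body) != n + 8:
        raise IndexCorruptionError(
            f"stream ends mid-entry at position {pos} "
            f"(needed {1 + n + 8} bytes, got {1 + len(body)})"
        )
    pointer = VirtualOffset.from_packed(_POINTER.unpack(body[n:])[0])
    return IndexEntry(body[:n], pointer)


class EntryWriter:
    """Write entries to a BGZF file, reporting each entry's virtual offset.

    The reported offset is where the entry *begins*, which is what the top
    index stores as its pointer into the data file.  Entries may straddle
    BGZF block boundaries; readers treat the file as one continuous byte
    stream.
    """

    def __init__(self, path: str | os.PathLike):
        self._path = os.fspath(path)
        self._writer = bgzf.BgzfWriter(self._path, "wb")
        self.count = 0

    def write(self, entry: IndexEntry) -> VirtualOffset:
        voffset = VirtualOffset.from_packed(self._writer.tell())
        self._writer.write(encode_entry(entry))
        self.count += 1
        if self._writer.tell() & 0xFFFF >= BLOCK_FLUSH_THRESHOLD:
            self._writer.flush()
        return voffset

    def close(self) -> None:
        self._writer.close()  # appends the BGZF EOF block

    def abort(self) -> None:
        """Close and remove the partial file after a failure."""
        try:
            self._writer.close()
        finally:
            if os.path.exists(self._path):
                os.unlink(self._path)

    def __enter__(self) -> "EntryWriter":
        return self

    def __exit__(self, exc_type, exc, tb) -> None:
        if exc_type is None:
            self.close()
        else:
            self.abort()


def write_entries(path: str | os.PathLike, entries: Iterable[IndexEntry]) -> int:
    """Write *entries* (already in final sorted order) as a BGZF file."""
    with EntryWriter(path) as writer:
        for entry in entries:
            writer.write(entry)
        return writer.count


def read_entries_from(
    path: str | os.PathLike,
    start: VirtualOffset | None = None,
) -> Iterator[Tuple[IndexEntry, VirtualOffset]]:
    """Yield ``(entry, voffset_of_entry)`` pairs in file order from *start*.

    *start* of ``None`` means the beginning of the file.  Iteration stops at
    the clean end of the BGZF payload; a payload ending mid-entry raises
    :class:`IndexCorruptionError`.
    """
    with bgzf.BgzfReader(os.fspath(path), "rb") as reader:
        if start is not None:
            try:
                reader.seek(start.packed)
            except ValueError as exc:
                raise IndexCorruptionError(
                    f"{path}: cannot seek to virtual offset {start} ({exc})"
                ) from exc
        while True:
            voffset = VirtualOffset.from_packed(reader.tell())
            try:
                entry = decode_entry(reader)
            except IndexCorruptionError as exc:
                raise IndexCorruptionError(f"{path}: {exc}") from None
            if entry is None:
                return
            yield entry, voffset
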