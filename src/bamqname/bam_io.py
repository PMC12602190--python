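"""BAM access by virtual offset.

BAM files are BGZF-compressed: a concatenation of independent gzip blocks,
each holding at most 64 KiB of uncompressed payload.  Any byte of the
uncompressed stream is addressable by a 64-bit *virtual offset* packing the
compressed file offset of its block (high 48 bits) with the offset inside
that block's payload (low 16 bits).  This module streams alignment records
together with the virtual offset at which each record starts, seeks back to
such an offset to decode a single record, and re-emits records as SAM text.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import IO, Iterable, Iterator, NamedTuple

import pysam

logger = logging.getLogger(__name__)

#: The 28-byte empty BGZF block that terminates every intact BGZF file
#: (and therefore every intact BAM).  Its absence signals truncation.
BGZF_EOF_MARKER = bytes.fromhex(
    "1f8b08040000000000ff0600424302001b0003000000000000000000"
)


class BamFormatError(Exception):
    """The input is not a readable BAM file."""


class TruncatedBamError(BamFormatError):
    """The BGZF EOF marker is missing: the file is (or may be) truncated."""


class RecordFetchError(Exception):
    """A virtual offset did not yield a decodable alignment record."""


class VirtualOffset(NamedTuple):
    """A 64-bit BGZF pointer: ``coffset << 16 | uoffset``.

    ``coffset`` is the byte offset of a BGZF block start within the
    compressed file (48 bits); ``uoffset`` is the byte offset within that
    block's uncompressed payload (16 bits).  Tuple ordering coincides with
    ordering of the packed 64-bit value.
    """

    coffset: int
    uoffset: int

    @property
    def packed(self) -> int:
        return (self.coffset << 16) | self.uoffset

    @classmethod
    def from_packed(cls, value: int) -> "VirtualOffset":
        if not 0 <= value < 1 << 64:
            raise ValueError(f"virtual offset {value} does not fit in 64 bits")
        return cls(value >> 16, value & 0xFFFF)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.coffset}:{self.uoffset}"


@dataclass
class AlignmentRecordRef:
    """One alignment record plus the virtual offset where it starts."""

    qname: bytes
    voffset: VirtualOffset
    record: pysam.AlignedSegment


def _record_qname(record: pysam.AlignedSegment) -> bytes:
    # An absent QNAME is represented as the literal "*" so that every
    # record remains retrievable (one index entry per record, no filter).
    name = record.query_name
    return name.encode("ascii") if name else b"*"


def has_bgzf_eof_marker(path: str | os.PathLike) -> bool:
    """True if *path* ends with the standard 28-byte BGZF EOF block."""
    with open(path, "rb") as fh:
        fh.seek(0, os.SEEK_END)
        size = fh.tell()
        if size < len(BGZF_EOF_MARKER):
            return False
        fh.seek(size - len(BGZF_EOF_MARKER))
        return fh.read(len(BGZF_EOF_MARKER)) == BGZF_EOF_MARKER


def open_bam(
    path: str | os.PathLike, threads: int = 1, ignore_truncation: bool = False
) -> pysam.AlignmentFile:
    """Open a BAM for reading, raising :class:`BamFormatError` on bad magic."""
    if not os.path.exists(path):
        raise BamFormatError(f"no such file: {path}")
    try:
        return pysam.AlignmentFile(
            os.fspath(path),
            "rb",
            check_sq=False,
            threads=max(1, threads),
            ignore_truncation=ignore_truncation,
        )
    except ValueError as exc:
        raise BamFormatError(f"{path}: not a BAM file ({exc})") from exc


def stream_records(
    bam_path: str | os.PathLike,
    *,
    threads: int = 1,
    on_truncated: str = "warn",
) -> Iterator[AlignmentRecordRef]:
    """Yield every alignment record of *bam_path* in file order.

    All records are yielded regardless of flags (unmapped, secondary,
    supplementary, duplicate).  Each ref carries the virtual offset of the
    record's first byte; seeking there with :func:`fetch_record` reproduces
    the record.

    Parameters
    ----------
    threads
        BGZF decompression worker threads (htslib); does not change the
        record order, only throughput.
    on_truncated
        ``"warn"`` processes whatever records are decodable from a file
        missing its BGZF EOF marker; ``"error"`` raises
        :class:`TruncatedBamError` instead.
    """
    if on_truncated not in ("warn", "error"):
        raise ValueError(f"on_truncated must be 'warn' or 'error', got {on_truncated!r}")
    truncated = not has_bgzf_eof_marker(bam_path)
    if truncated:
        if on_truncated == "error":
            raise TruncatedBamError(
                f"{bam_path}: BGZF EOF marker missing; refusing to proceed "
                "(the file may be truncated)"
            )
        logger.warning(
            "%s: BGZF EOF marker missing; processing available records", bam_path
        )
    with open_bam(bam_path, threads=threads, ignore_truncation=truncated) as bam:
        while True:
            voffset = VirtualOffset.from_packed(bam.tell())
            try:
                record = next(bam)
            except StopIteration:
                break
            except OSError as exc:
                raise BamFormatError(f"{bam_path}: decode failure ({exc})") from exc
            yield AlignmentRecordRef(_record_qname(record), voffset, record)


class BamFetcher:
    """Random access to single records of one BAM by virtual offset.

    Keeps the file handle open across fetches; fetches may arrive in any
    order and repeat.
    """

    def __init__(self, bam_path: str | os.PathLike):
        self._path = os.fspath(bam_path)
        self._bam = open_bam(bam_path)
        # tell() straight after the header parse = first possible record
        # offset; anything below it points into the header.
        self._first_record_voffset = self._bam.tell()

    @property
    def header(self) -> pysam.AlignmentHeader:
        return self._bam.header

    def fetch(self, v: VirtualOffset) -> pysam.AlignedSegment:
        packed = v.packed
        if packed < self._first_record_voffset:
            raise RecordFetchError(
                f"{self._path}: virtual offset {v} points inside the BAM header, "
                "not at a record"
            )
        try:
            self._bam.seek(packed)
            return next(self._bam)
        except StopIteration:
            raise RecordFetchError(
                f"{self._path}: virtual offset {v} is at or beyond end of file"
            ) from None
        except (OSError, ValueError) as exc:
            raise RecordFetchError(
                f"{self._path}: cannot decode a record at virtual offset {v} ({exc})"
            ) from exc

    def close(self) -> None:
        self._bam.close()

    def __enter__(self) -> "BamFetcher":
        return self

    def __exit__(self, *exc_info) -> None:
        self.close()


def fetch_record(bam_path: str | os.PathLike, v: VirtualOffset) -> pysam.AlignedSegment:
    """Decode the single alignment record starting at virtual offset *v*."""
    with BamFetcher(bam_path) as fetcher:
        return fetcher.fetch(v)


def read_header(bam_path: str | os.PathLike) -> pysam.AlignmentHeader:
    with open_bam(bam_path) as bam:
        return bam.header


def emit_sam(
    header: pysam.AlignmentHeader,
    records: Iterable[pysam.AlignedSegment],
    destination: IO[str],
    *,
    with_header: bool = True,
) -> None:
    """Write a SAM document: header lines first, then one line per record.

    Output is byte-stable for fixed input; records are written in the order
    given.
    """
    if with_header:
        destination.write(str(header))
    for record in records:
        destination.write(record.to_string())
        destination.write("\n")
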