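"""Three-step qname search over the two-level index.

1. Binary-search the small, in-memory top index for the last entry sorting
   strictly below the query (see :func:`find_scan_start` for why strict);
   its pointer is where the data-file scan starts.
2. Scan the data file forward from that offset, collecting the BAM virtual
   offsets of entries whose qname equals the query, stopping at the first
   greater qname (sortedness guarantees no later matches).  At most about
   sqrt(N) entries are decoded, plus the matches themselves.
3. Seek to each collected virtual offset in the BAM and decode the record.

Exact bytewise qname equality only; all records carrying the qname are
returned (mates, secondary, supplementary, duplicates alike).  A query below
the smallest indexed qname is answered "absent" without touching the disk.
"""

from __future__ import annotations

import os
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import pysam
from Bio import bgzf

from .bam_io import BamFetcher, RecordFetchError, VirtualOffset
from .index_format import (
    IndexCorruptionError,
    IndexEntry,
    IndexPair,
    decode_entry,
    read_entries_from,
)


class MissingIndexError(Exception):
    """No index directory for this BAM; run the index step first."""


class StaleIndexError(Exception):
    """An indexed offset no longer decodes: the BAM changed after indexing."""


@dataclass
class QueryResult:
    """All records matching one queried qname, with provenance offsets.

    ``scan_count`` is the number of data-file entries decoded while serving
    this query; it is bounded by sampling_interval(N) + matches + 1.
    """

    qname: bytes
    offsets: List[VirtualOffset] = field(default_factory=list)
    records: List[pysam.AlignedSegment] = field(default_factory=list)
    scan_count: int = 0

    @property
    def found(self) -> bool:
        return bool(self.offsets)


def load_top_index(top_path: str | os.PathLike) -> List[IndexEntry]:
    """Read the whole top index into memory, verifying it is sorted."""
    entries = [entry for entry, _ in read_entries_from(top_path)]
    for prev, cur in zip(entries, entries[1:]):
        if cur.sort_key < prev.sort_key:
            raise IndexCorruptionError(
                f"{top_path}: entries out of order ({prev.qname!r} then "
                f"{cur.qname!r}); rebuild the index"
            )
    return entries


def find_scan_start(
    top: Sequence[IndexEntry], qname: bytes
) -> Optional[VirtualOffset]:
    """Data-file offset from which the bounded scan must start, or None.

    Returns the pointer of the last top entry whose qname sorts *strictly
    below* the query.  Starting strictly below matters when qnames repeat
    (read pairs, secondary alignments): a sampled entry equal to the query
    may sit in the middle of that qname's run of data entries, so starting
    at it would skip the run's earlier records, whereas no match can
    precede a strictly smaller key.  The scanned window still spans at most
    one sampling stride plus the matches themselves.

    When the query equals the very first top qname (the minimum of the key
    space — the first data entry is always promoted) the scan starts at the
    file start.  None means the query cannot be in the index at all: the
    top index is empty, or the query sorts below the smallest indexed
    qname.
    """
    i = bisect_left(top, qname, key=lambda e: e.qname)
    if i > 0:
        return top[i - 1].pointer
    if top and top[0].qname == qname:
        return top[0].pointer
    return None


def scan_data(
    data_path: str | os.PathLike,
    start: VirtualOffset,
    qname: bytes,
) -> Tuple[List[VirtualOffset], int]:
    """Collect BAM offsets of all data entries matching *qname*.

    Decodes entries sequentially from *start* and stops at the first entry
    whose qname exceeds the query, or at end of file.  Returns the matches
    (ascending, possibly empty) and the number of entries decoded.
    """
    matches: List[VirtualOffset] = []
    scanned = 0
    for entry, _ in read_entries_from(data_path, start):
        scanned += 1
        if entry.qname == qname:
            matches.append(entry.pointer)
        elif entry.qname > qname:
            break
    return matches, scanned


class _DataScanner:
    """Sequential data-file scanner reusing one open BGZF handle."""

    def __init__(self, data_path: str | os.PathLike):
        self._reader = bgzf.BgzfReader(os.fspath(data_path), "rb")
        self._path = os.fspath(data_path)

    def scan(self, start: VirtualOffset, qname: bytes) -> Tuple[List[VirtualOffset], int]:
        self._reader.seek(start.packed)
        matches: List[VirtualOffset] = []
        scanned = 0
        while True:
            try:
                entry = decode_entry(self._reader)
            except IndexCorruptionError as exc:
                raise IndexCorruptionError(f"{self._path}: {exc}") from None
            if entry is None:
                break
            scanned += 1
            if entry.qname == qname:
                matches.append(entry.pointer)
            elif entry.qname > qname:
                break
        return matches, scanned

    def close(self) -> None:
        self._reader.close()


def _as_qname_bytes(qname: bytes | str) -> bytes:
    return qname.encode("ascii") if isinstance(qname, str) else qname


def query(
    bam_path: str | os.PathLike,
    index: IndexPair | None = None,
    qnames: Iterable[bytes | str] = (),
) -> List[QueryResult]:
    """Answer a batch of qname queries against one indexed BAM.

    Results come back in input order, one per input qname (duplicates each
    answered, unknown qnames yield empty results).  Internally the batch is
    served in sorted qname order so the data-file scans move forward, then
    re-emitted in input order.
    """
    index = index or IndexPair.locate(bam_path)
    if not index.exists():
        raise MissingIndexError(
            f"no index at {index.directory}; run the index step for {bam_path} first"
        )
    wanted = [_as_qname_bytes(q) for q in qnames]
    top = load_top_index(index.top_path)
    results: List[Optional[QueryResult]] = [None] * len(wanted)

    scanner = _DataScanner(index.data_path)
    try:
        with BamFetcher(bam_path) as fetcher:
            for i in sorted(range(len(wanted)), key=lambda i: wanted[i]):
                q = wanted[i]
                result = QueryResult(qname=q)
                start = find_scan_start(top, q)
                if start is not None:
                    result.offsets, result.scan_count = scanner.scan(start, q)
                    for offset in result.offsets:
                        try:
                            result.records.append(fetcher.fetch(offset))
                        except RecordFetchError as exc:
                            raise StaleIndexError(
                                f"indexed offset {offset} no longer decodes — was "
                                f"{bam_path} modified after indexing? ({exc})"
                            ) from exc
                results[i] = result
    finally:
        scanner.close()
    return [r for r in results if r is not None]
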