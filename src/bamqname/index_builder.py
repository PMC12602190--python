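"""Build the two-level qname index from a BAM file.

The build streams the BAM exactly once, producing one ``(qname, virtual
offset)`` entry per alignment record.  Entries are sorted by qname with an
external merge sort (sorted runs spilled to temporary BGZF files, merged
k-way) so memory stays bounded on arbitrarily large BAMs.  The sorted stream
is written to ``qname.v3.data.bgz`` and, in the same pass, every k-th entry
— with k = ceil(sqrt(N)), so about sqrt(N) entries in total — is promoted
into ``qname.v3.index.bgz`` with a pointer to its position in the data
file.  Indexing cost is therefore linear in the record count N, and the
sampled top index is what makes per-query search cost proportional to
sqrt(N).
"""

from __future__ import annotations

import heapq
import logging
import math
import os
import shutil
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, List, Tuple

from . import bam_io
from .bam_io import VirtualOffset
from .index_format import (
    EntryWriter,
    IndexEntry,
    IndexFormatError,
    IndexPair,
    MAX_QNAME_LEN,
    read_entries_from,
    write_entries,
)

logger = logging.getLogger(__name__)

#: Serialized entry size is 9 + len(qname); budget accounting uses this.
_ENTRY_OVERHEAD = 9


class IndexExistsError(Exception):
    """The index directory already exists; pass force=True to rebuild."""


@dataclass
class BuildConfig:
    """Resource knobs for an index build.

    memory_budget
        Approximate bytes of serialized entries held per in-memory sort
        chunk before spilling a sorted run to disk.  512 MiB default; tests
        shrink it to force spills.
    workers
        BGZF decompression worker threads for reading the BAM.  The final
        index bytes are identical for any worker count.
    temp_dir
        Where spill runs are written (a private subdirectory is created and
        always removed).  Defaults to the system temp directory.
    """

    memory_budget: int = 512 * 1024 * 1024
    workers: int = 1
    temp_dir: str | os.PathLike | None = None
    allow_truncated: bool = False

    def __post_init__(self) -> None:
        if self.memory_budget < _ENTRY_OVERHEAD + 1:
            raise ValueError("memory_budget must hold at least one entry")
        if self.workers < 1:
            raise ValueError("workers must be >= 1")


def sampling_interval(n: int) -> int:
    """Promotion stride k = max(1, ceil(sqrt(n))) for n data entries.

    Every k-th data entry (the first always included) goes into the top
    index, giving ceil(n/k) ~ sqrt(n) top entries.
    """
    if n < 0:
        raise ValueError("entry count cannot be negative")
    if n == 0:
        return 1
    root = math.isqrt(n)
    return root if root * root == n else root + 1


def parallel_extract(
    bam_path: str | os.PathLike,
    workers: int = 1,
    *,
    on_truncated: str = "error",
) -> Iterator[IndexEntry]:
    """Stream one IndexEntry per BAM record, in file order.

    Parallelism is htslib's multi-threaded BGZF decompression, which leaves
    the record order untouched: any worker count yields the identical entry
    stream, so the final index is byte-identical across worker counts.
    """
    for ordinal, ref in enumerate(
        bam_io.stream_records(bam_path, threads=workers, on_truncated=on_truncated)
    ):
        if not 1 <= len(ref.qname) <= MAX_QNAME_LEN:
            raise IndexFormatError(
                f"record #{ordinal} has a qname of {len(ref.qname)} bytes "
                f"(allowed 1..{MAX_QNAME_LEN})"
            )
        yield IndexEntry(ref.qname, ref.voffset)


def _spill_run(entries: List[IndexEntry], temp_dir: str) -> str:
    entries.sort(key=lambda e: e.sort_key)
    fd, path = tempfile.mkstemp(suffix=".run.bgz", dir=temp_dir)
    os.close(fd)
    write_entries(path, entries)
    return path


def _sorted_runs(
    entries: Iterable[IndexEntry], config: BuildConfig, temp_dir: str
) -> Tuple[int, List[str], List[IndexEntry]]:
    """Consume *entries* into sorted spill runs plus a final in-memory chunk.

    Returns (total count, run paths, sorted in-memory tail chunk)."""
    runs: List[str] = []
    chunk: List[IndexEntry] = []
    chunk_bytes = 0
    total = 0
    for entry in entries:
        chunk.append(entry)
        chunk_bytes += _ENTRY_OVERHEAD + len(entry.qname)
        total += 1
        if chunk_bytes >= config.memory_budget:
            runs.append(_spill_run(chunk, temp_dir))
            chunk = []
            chunk_bytes = 0
    chunk.sort(key=lambda e: e.sort_key)
    return total, runs, chunk


def _merge_runs(runs: List[str], tail: List[IndexEntry]) -> Iterator[IndexEntry]:
    streams = [(entry for entry, _ in read_entries_from(path)) for path in runs]
    streams.append(iter(tail))
    return heapq.merge(*streams, key=lambda e: e.sort_key)


def external_sort(
    entries: Iterable[IndexEntry], config: BuildConfig | None = None
) -> Iterator[IndexEntry]:
    """Sort an entry stream by (qname bytes, pointer) within a memory budget.

    Chunks up to the budget are sorted in memory; further input spills as
    sorted BGZF runs that are k-way merged.  With everything in budget this
    degenerates to a plain in-memory sort with no spill files.
    """
    config = config or BuildConfig()
    temp_root = tempfile.mkdtemp(
        prefix="bamqname-sort-",
        dir=os.fspath(config.temp_dir) if config.temp_dir else None,
    )
    try:
        _, runs, tail = _sorted_runs(entries, config, temp_root)
        yield from _merge_runs(runs, tail)
    finally:
        shutil.rmtree(temp_root, ignore_errors=True)


def build_index(
    bam_path: str | os.PathLike,
    config: BuildConfig | None = None,
    *,
    index_dir: str | os.PathLike | None = None,
    force: bool = False,
) -> Tuple[IndexPair, int, int]:
    """Create both index files for *bam_path*.

    Returns ``(pair, n_data_entries, n_top_entries)``.  The data file holds
    exactly one sorted entry per BAM record; the top file holds every k-th
    of them (k = ceil(sqrt(N))) pointing at its data-file offset.  The build
    is deterministic: same input and config give the same uncompressed index
    bytes regardless of worker count.
    """
    config = config or BuildConfig()
    if not os.path.exists(bam_path):
        raise bam_io.BamFormatError(f"no such file: {bam_path}")
    pair = IndexPair.locate(bam_path, index_dir)
    if pair.directory.exists():
        if not force:
            raise IndexExistsError(
                f"{pair.directory} already exists; use force to rebuild"
            )
        shutil.rmtree(pair.directory)
    pair.directory.mkdir(parents=True)

    temp_root = tempfile.mkdtemp(
        prefix="bamqname-build-",
        dir=os.fspath(config.temp_dir) if config.temp_dir else None,
    )
    try:
        extracted = parallel_extract(
            bam_path,
            config.workers,
            on_truncated="warn" if config.allow_truncated else "error",
        )
        total, runs, tail = _sorted_runs(extracted, config, temp_root)
        k = sampling_interval(total)

        top_entries: List[IndexEntry] = []
        with EntryWriter(pair.data_path) as writer:
            for i, entry in enumerate(_merge_runs(runs, tail)):
                data_offset = writer.write(entry)
                if i % k == 0:
                    top_entries.append(IndexEntry(entry.qname, data_offset))
        write_entries(pair.top_path, top_entries)
    except BaseException:
        shutil.rmtree(pair.directory, ignore_errors=True)
        raise
    finally:
        shutil.rmtree(temp_root, ignore_errors=True)

    logger.debug(
        "indexed %s: %d data entries, %d top entries (interval %d) in %s",
        bam_path, total, len(top_entries), k, pair.directory,
    )
    return pair, total, len(top_entries)
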