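# Methods

## The retrieval problem and the index model

A BAM file stores alignment records in BGZF compression: a sequence of
independent gzip blocks of at most 64 KiB uncompressed payload. Any byte of
the logical record stream is addressable by a 64-bit *virtual offset*
packing the compressed offset of its block (48 bits) and the offset inside
the block's payload (16 bits); seeking to a record's virtual offset and
decoding one record is O(one block). Coordinate indexes (BAI/CSI) exploit
this for positional queries but provide nothing for the read identifier
(QNAME), which is where this package intervenes.

The index is a classic two-level sparse index over sorted string keys:

* **data file** — one `(qname, BAM virtual offset)` entry per alignment
  record, sorted by qname (bytewise) with ties by ascending offset, stored
  as BGZF;
* **top index** — every k-th data entry, k = ⌈√N⌉, each pointing at its own
  position in the data file; ⌈N/k⌉ ≈ √N entries, small enough to hold in
  memory (a few MB even for a 10⁹-record BAM).

A query binary-searches the in-memory top index (O(log √N)), scans at most
one sampling stride of the data file sequentially (O(√N) entry decodes),
and fetches each matching record directly from the BAM by virtual offset.
Choosing k = ⌈√N⌉ balances the two level sizes; any fixed k trades top-index
memory against scan length, and √N is the minimizer of their sum.

Every record is indexed — unmapped, secondary, supplementary and
duplicate-flagged records alike, and records without a read name under the
literal key `*` — because retrieval by identifier is only trustworthy if it
is total. Matching is exact bytewise equality; all records carrying the
qname are returned in file order.

## Scan-start rule under duplicate keys

Qnames are not unique: a read pair shares one qname across two primary
records, and secondary/supplementary alignments add more. This forces one
non-obvious design decision. The top index samples every k-th *entry*, so a
sampled entry can fall in the middle of a run of equal qnames. Two naive
rules both fail:

* *"Start the scan at the last sampled entry ≤ query"* — if the sampled
  entry equals the query and sits mid-run, the run's earlier records are
  silently missed: wrong results.
* *"Point sampled entries at their run's first entry"* — correct, but the
  scan for a query landing late in the next stride then decodes up to the
  rewind distance extra, breaking the per-query bound
  `scan_count ≤ ⌈√N⌉ + matches + 1` (for an absent query just below a
  sampled key whose promotion was rewound, the scan covers a full stride
  plus the rewind).

The implemented rule keeps exact promoted-position pointers and starts the
scan at the last sampled entry sorting **strictly below** the query, falling
back to the file start when the query equals the smallest key (the first
entry is always promoted, so the minimum is always sampled). No match can
precede a strictly smaller key, so correctness is unconditional; and the
scanned window is provably at most one stride plus the matches themselves,
so `scan_count ≤ ⌈√N⌉ + matches + 1` holds for every query, duplicated keys
or not. The cost is that a query exactly equal to a sampled key starts one
stride early — still within the same bound. The top-index cardinality stays
exactly ⌈N/k⌉.

## Index construction

The build streams the BAM exactly once, in file order, collecting
`(qname, virtual offset)` pairs. Sorting uses an external merge sort:
entries accumulate up to a configurable serialized-byte budget (default
512 MiB), each full chunk is sorted and spilled as a BGZF run reusing the
index-file codec, and the runs plus the in-memory tail are merged k-way
lazily. The sorted stream is written to the data file in a single pass
during which every k-th entry is promoted, capturing its just-written
data-file offset; k is known because the sort's consume phase counts N
before the merge phase emits anything. Temp runs are always deleted, and a
failed build removes the half-written index directory.

Multi-worker builds (`--workers`) attach htslib's BGZF decompression thread
pool to the BAM reader. Decompression threads change throughput, never
record order, so the entry stream — and therefore the final index — is
byte-identical for any worker count; the test suite asserts this equality
rather than any hardware-dependent speedup.

Determinism extends to compressed bytes: the index writer flushes a BGZF
block once ≥60,000 uncompressed bytes are buffered, a fixed policy chosen
below the 64 KiB format ceiling (so a compressed block can never overflow
the 16-bit block-size field even on incompressible input) and high enough
to keep compression ratios close to full blocks.

## Parameters

| parameter | default | meaning |
|---|---|---|
| sampling interval k | ⌈√N⌉, N = record count | top-index stride; fixed by the model, not user-tunable |
| `memory_budget` | 512 MiB | serialized entry bytes per in-memory sort chunk before spilling |
| `workers` | 1 | BGZF decompression threads for the BAM reader |
| block flush threshold | 60,000 B | uncompressed bytes per index BGZF block |
| qname length | 1–254 B | SAM's QNAME cap, enforced at encode time |

## Error handling and degenerate inputs

A BAM missing its 28-byte BGZF EOF marker may be silently truncated, and an
index over a truncated file would lie about the file's contents, so `index`
fails fast by default; `--allow-truncated` downgrades to a warning and
indexes the decodable prefix. An empty BAM yields two valid BGZF files of
zero entries, and every query then reports absent. Queries below the
smallest indexed qname short-circuit to absent without touching the disk.
Corrupt index files (entries out of order, payload ending mid-entry) raise
a dedicated corruption error telling the user to rebuild, never a wrong
answer. An existing index directory is refused without `--force` so a stale
index cannot be half-overwritten.

## Synthetic data: what it does and does not model

The generator produces structurally realistic BAMs: Illumina-style
colon-delimited qnames with 150 bp paired reads, UUID-style qnames with
~20 kb single-end reads, or single-letter qnames for worked examples;
configurable fractions of unmapped templates and secondary alignments;
records written in a seeded shuffle so the index sort is a genuine
transformation; and a manifest of per-qname expected counts and flags that
serves as ground truth. Sequences are uniform random ACGT — no error
models, quality realism, or aligner behavior — because the index never
inspects bases; what the tests therefore demonstrate is correctness of
indexing and retrieval over realistic *file structure* (key shapes,
duplicate multiplicities, flag combinations, multi-block files), not
anything about biological signal. Real-world concerns the synthetic data
does not exercise: CRAM inputs (out of scope), qnames in non-ASCII
encodings (SAM forbids them), and files larger than memory (covered
logically by forcing the external sort to spill, not by writing huge
files).

Test and acceptance problem sizes — ~10,000 records for the short-read
regime, 1,000 for the long-read regime, 200 queries per regime — were
chosen as the smallest sizes at which the index spans many BGZF blocks,
every flag class appears, and the √N machinery (stride ~100) is
non-trivially exercised.

## Known limitations

* No compatibility claim with any previously published index of the same
  directory layout: the entry byte layout matches, but block framing and
  tie-breaking of equal qnames are this package's own fixed choices.
* The data file is rewritten from scratch on rebuild; there is no
  incremental append.
* Retrieval is exact-match only — no prefix, range, or regex queries — and
  there is no flag-based filtering; downstream tools can filter the SAM.
* Output is SAM text only (header included by default, `--no-header` to
  drop it); writing BAM back is out of scope.
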