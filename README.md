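# bamqname

Retrieve DNA/RNA sequencing reads from a BAM file by their **read
identifier (qname)** — the one access path standard tooling does not index.

`samtools` and friends answer "which reads cover chr7:140,453,136?" in
milliseconds through coordinate indexes (BAI/CSI), but "show me every record
for read `A01221:43:HVKW3DSXY:3:2506:15845:19633`" forces a full linear scan
of the file — minutes to half an hour on a whole-genome BAM, which makes
read-level analyses (cross-build mapping comparisons, viral-integration
hunting, structural-variant curation) infeasible at scale. `bamqname` fixes
this with a one-time indexing pass and near-instant lookups afterwards.

## How it works

BAM files are BGZF-compressed: independent gzip blocks of ≤64 KiB, so any
record is addressable by a 64-bit **virtual offset**
`voffset = coffset << 16 | uoffset` (compressed block start, offset within
the block's payload). Indexing streams the BAM once and writes a directory
`<bam>.atlantool-index/` containing two BGZF files built from one record
layout — a 1-byte qname length, the qname bytes, and an 8-byte little-endian
pointer:

* `qname.v3.data.bgz` — one entry per alignment record (including unmapped,
  secondary, supplementary and duplicate-flagged ones), sorted bytewise by
  qname with ties broken by ascending BAM virtual offset. Sorting uses an
  external merge sort, so memory stays bounded on arbitrarily large BAMs.
* `qname.v3.index.bgz` — every k-th data entry, k = ⌈√N⌉ for N records,
  giving ⌈N/k⌉ ≈ √N sampled entries whose pointers are data-file offsets.

A query loads only the small top file into memory, binary-searches it for
the scan start, decodes at most ~√N data entries on disk to collect the
matching BAM offsets, and seeks straight to each record. Indexing cost is
O(N); per-query cost is O(√N): the search decodes at most
`⌈√N⌉ + matches + 1` index entries, a property the test suite asserts for
every query it runs.

## Worked example

```
$ python - <<'EOF'
from bamqname import GeneratorSpec, generate_bam
generate_bam(GeneratorSpec(n_templates=1000, paired=True,
                           qname_style="illumina", seed=5), "example.bam")
EOF

$ bamqname index example.bam
[bamqname] indexed 2000 records (45 top-index entries)
  data: example.bam.atlantool-index/qname.v3.data.bgz
  top:  example.bam.atlantool-index/qname.v3.index.bgz

$ bamqname view example.bam -n SIM100:7:HXSIMDSXY:3:1101:36885:3 --verbose
[bamqname] SIM100:7:HXSIMDSXY:3:1101:36885:3: 2 record(s), 46 entries scanned
@HD     VN:1.6  SO:unsorted
@SQ     SN:chr1 LN:1000000
@SQ     SN:chr2 LN:800000
SIM100:7:HXSIMDSXY:3:1101:36885:3       99      chr1    596295  60      150M    =       596295  0       AAACAGAAA...
SIM100:7:HXSIMDSXY:3:1101:36885:3       147     chr1    596723  60      150M    =       596723  0       CGGCCCAAG...
```

The 2,000-record BAM gets a 45-entry top index (⌈2000/45⌉ = 45, k = ⌈√2000⌉
= 45). The queried template is a proper pair, so `view` prints the SAM
header followed by exactly two alignment lines — mate 1 (flag 99) and mate 2
(flag 147) — and the verbose log shows the bounded search: 46 index entries
decoded (≤ k + matches + 1 = 48) instead of a 2,000-record scan. Batch
retrieval reads qnames from a file, one per line:
`bamqname view example.bam -f qnames.txt > out.sam`. Unknown qnames are
reported as a warning on stderr, never an error: absence of a read is an
answer.

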