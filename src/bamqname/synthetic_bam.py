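"""Deterministic synthetic BAM generator and brute-force retrieval oracle.

Generates structurally realistic BAMs covering the regimes the index must
handle — short paired Illumina-style reads (colon-delimited qnames, 150 bp),
long single-end reads (UUID-style qnames, ~20 kb), and tiny letter-qname
toys for worked examples — plus configurable fractions of unmapped and
secondary records.  No biological realism is claimed: sequences are uniform
random ACGT and positions are uniform over the reference.  What matters for
index testing is structural realism: qname shapes and multiplicity, flag
combinations, record sizes spanning many BGZF blocks, and a seeded shuffle
of the write order so that sorting the index is a genuine transformation.

The returned manifest (qname -> expected record count and flags) is the test
oracle for everything downstream, and :func:`brute_force_lookup` — a plain
linear scan — is the intentionally simple reference against which the
indexed search is checked for equivalence.
"""

from __future__ import annotations

import os
import random
import uuid
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import pysam

_BASES = "ACGT"

# flag bits
_PAIRED = 0x1
_PROPER = 0x2
_UNMAPPED = 0x4
_MATE_UNMAPPED = 0x8
_REVERSE = 0x10
_MATE_REVERSE = 0x20
_READ1 = 0x40
_READ2 = 0x80
_SECONDARY = 0x100


@dataclass
class GeneratorSpec:
    """Parameters of one synthetic BAM.

    ``qname_style`` is one of ``illumina`` (instrument:run:flowcell:lane:
    tile:x:y), ``uuid`` (long-read style), or ``letters`` (single uppercase
    letters, for small worked-example fixtures; caps n_templates at 26).
    All qnames are unique across templates; with ``paired`` each qname
    appears on exactly two primary records.  The seed fully determines the
    output bytes.
    """

    n_templates: int
    paired: bool = False
    read_length: int = 150
    qname_style: str = "illumina"
    seed: int = 0
    references: Tuple[Tuple[str, int], ...] = (
        ("chr1", 1_000_000),
        ("chr2", 800_000),
    )
    fraction_unmapped: float = 0.0
    fraction_secondary: float = 0.0

    def __post_init__(self) -> None:
        if self.qname_style not in ("illumina", "uuid", "letters"):
            raise ValueError(f"unknown qname_style {self.qname_style!r}")
        if self.qname_style == "letters" and self.n_templates > 26:
            raise ValueError("letters style supports at most 26 templates")
        if not 0 <= self.fraction_unmapped <= 1:
            raise ValueError("fraction_unmapped must be in [0, 1]")
        if not 0 <= self.fraction_secondary <= 1:
            raise ValueError("fraction_secondary must be in [0, 1]")


@dataclass
class Manifest:
    """Per-qname expectations recorded while writing the BAM."""

    counts: Dict[str, int] = field(default_factory=dict)
    flags: Dict[str, List[int]] = field(default_factory=dict)

    @property
    def total_records(self) -> int:
        return sum(self.counts.values())

    def write_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as out:
            for qname in sorted(self.counts):
                joined = ",".join(str(f) for f in self.flags[qname])
                out.write(f"{qname}\t{self.counts[qname]}\t{joined}\n")


def _make_qname(style: str, i: int, rng: random.Random) -> str:
    if style == "letters":
        return chr(ord("A") + i)
    if style == "illumina":
        tile = 1101 + (i // 10_000)
        x = rng.randrange(1000, 60_000)
        return f"SIM100:7:HXSIMDSXY:3:{tile}:{x}:{i}"
    # uuid: random bits XORed with the template ordinal to guarantee
    # uniqueness without a global seen-set
    return str(uuid.UUID(int=rng.getrandbits(128) ^ i))


def _random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choices(_BASES, k=length))


def _new_record(
    header: pysam.AlignmentHeader,
    qname: str,
    flag: int,
    seq: str,
    ref_id: int,
    pos: int,
    mapq: int,
) -> pysam.AlignedSegment:
    rec = pysam.AlignedSegment(header)
    rec.query_name = qname
    rec.flag = flag
    rec.query_sequence = seq
    rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    if flag & _UNMAPPED:
        rec.reference_id = -1
        rec.reference_start = -1
        rec.mapping_quality = 0
    else:
        rec.reference_id = ref_id
        rec.reference_start = pos
        rec.mapping_quality = mapq
        rec.cigarstring = f"{len(seq)}M"
    if flag & _PAIRED:
        if flag & (_MATE_UNMAPPED | _UNMAPPED):
            rec.next_reference_id = rec.reference_id
            rec.next_reference_start = rec.reference_start
        else:
            rec.next_reference_id = ref_id
            rec.next_reference_start = pos
    return rec


def generate_bam(spec: GeneratorSpec, out: str | os.PathLike) -> Manifest:
    """Write a BAM realizing *spec*; return the per-qname manifest.

    Records are written in a seeded shuffle of template order, so the file
    is never qname-sorted by accident.  Same spec and seed give byte-
    identical output.
    """
    rng = random.Random(spec.seed)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": name, "LN": length} for name, length in spec.references],
        }
    )
    manifest = Manifest()
    records: List[pysam.AlignedSegment] = []

    for i in range(spec.n_templates):
        qname = _make_qname(spec.qname_style, i, rng)
        unmapped = rng.random() < spec.fraction_unmapped
        secondary = rng.random() < spec.fraction_secondary
        ref_id = rng.randrange(len(spec.references))
        ref_len = spec.references[ref_id][1]
        span = max(1, ref_len - spec.read_length)
        pos = rng.randrange(span)
        seq = _random_seq(rng, spec.read_length)
        flags: List[int] = []

        if spec.paired:
            mate_pos = min(pos + spec.read_length + rng.randrange(300), span - 1)
            if unmapped:
                f1 = _PAIRED | _UNMAPPED | _MATE_UNMAPPED | _READ1
                f2 = _PAIRED | _UNMAPPED | _MATE_UNMAPPED | _READ2
            else:
                f1 = _PAIRED | _PROPER | _MATE_REVERSE | _READ1
                f2 = _PAIRED | _PROPER | _REVERSE | _READ2
            records.append(_new_record(header, qname, f1, seq, ref_id, pos, 60))
            seq2 = _random_seq(rng, spec.read_length)
            records.append(_new_record(header, qname, f2, seq2, ref_id, mate_pos, 60))
            flags += [f1, f2]
        else:
            if unmapped:
                f = _UNMAPPED
            else:
                f = _REVERSE if rng.random() < 0.5 else 0
            records.append(_new_record(header, qname, f, seq, ref_id, pos, 60))
            flags.append(f)

        if secondary and not unmapped:
            alt_pos = rng.randrange(span)
            fs = (flags[0] & ~_PROPER) | _SECONDARY
            records.append(_new_record(header, qname, fs, seq, ref_id, alt_pos, 0))
            flags.append(fs)

        manifest.counts[qname] = len(flags)
        manifest.flags[qname] = flags

    shuffle_rng = random.Random(spec.seed ^ 0x5DEECE66D)
    shuffle_rng.shuffle(records)

    with pysam.AlignmentFile(os.fspath(out), "wb", header=header) as bam:
        for rec in records:
            bam.write(rec)
    return manifest


def brute_force_lookup(
    bam_path: str | os.PathLike, qname: str | bytes
) -> List[pysam.AlignedSegment]:
    """Linear scan of the whole BAM for exact qname matches, in file order.

    Deliberately simple and slow: the correctness oracle for the indexed
    search path.
    """
    want = qname.decode("ascii") if isinstance(qname, bytes) else qname
    hits: List[pysam.AlignedSegment] = []
    with pysam.AlignmentFile(os.fspath(bam_path), "rb", check_sq=False) as bam:
        for rec in bam.fetch(until_eof=True):
            if (rec.query_name or "*") == want:
                hits.append(rec)
    return hits
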