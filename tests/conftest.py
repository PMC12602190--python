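"""Shared fixtures: synthetic BAMs and their built indexes.

The expensive fixtures (the ~10,000-record short-read build and the
1,000-record long-read build) are session-scoped so the whole suite pays
for them once.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List

import pytest

from bamqname import (
    BuildConfig,
    GeneratorSpec,
    IndexPair,
    build_index,
    generate_bam,
)
from bamqname.synthetic_bam import Manifest


@dataclass
class BuiltBam:
    """A generated BAM plus its manifest and built index."""

    bam: Path
    manifest: Manifest
    pair: IndexPair
    n_entries: int
    n_top: int

    def qnames(self) -> List[str]:
        return list(self.manifest.counts)


def _build(tmp: Path, spec: GeneratorSpec, name: str) -> BuiltBam:
    bam = tmp / name
    manifest = generate_bam(spec, bam)
    pair, n, ntop = build_index(bam)
    return BuiltBam(bam, manifest, pair, n, ntop)


@pytest.fixture(scope="session")
def letters_build(tmp_path_factory) -> BuiltBam:
    """Eight paired letter-qname templates (A..H): the worked-example toy."""
    tmp = tmp_path_factory.mktemp("letters")
    spec = GeneratorSpec(
        n_templates=8, paired=True, read_length=50, qname_style="letters", seed=7
    )
    return _build(tmp, spec, "letters.bam")


@pytest.fixture(scope="session")
def small_build(tmp_path_factory) -> BuiltBam:
    """500 Illumina-style pairs with secondaries and unmapped templates."""
    tmp = tmp_path_factory.mktemp("small")
    spec = GeneratorSpec(
        n_templates=500,
        paired=True,
        read_length=150,
        qname_style="illumina",
        seed=11,
        fraction_secondary=0.1,
        fraction_unmapped=0.05,
    )
    return _build(tmp, spec, "small.bam")


@pytest.fixture(scope="session")
def short_read_build(tmp_path_factory) -> BuiltBam:
    """5,000 Illumina-style pairs, 5% secondary, 2% unmapped (~10,250 records)."""
    tmp = tmp_path_factory.mktemp("short")
    spec = GeneratorSpec(
        n_templates=5_000,
        paired=True,
        read_length=150,
        qname_style="illumina",
        seed=20259,
        fraction_secondary=0.05,
        fraction_unmapped=0.02,
    )
    return _build(tmp, spec, "short.bam")


@pytest.fixture(scope="session")
def exact_10k_build(tmp_path_factory) -> BuiltBam:
    """Exactly 10,000 records (5,000 pairs, no extra secondaries):
    the round-number case where k = 100 and the top index has 100 entries."""
    tmp = tmp_path_factory.mktemp("exact10k")
    spec = GeneratorSpec(
        n_templates=5_000,
        paired=True,
        read_length=150,
        qname_style="illumina",
        seed=40961,
        fraction_unmapped=0.02,
    )
    return _build(tmp, spec, "exact10k.bam")


@pytest.fixture(scope="session")
def long_read_build(tmp_path_factory) -> BuiltBam:
    """1,000 single-end ~20 kb reads with UUID qnames (long-read regime)."""
    tmp = tmp_path_factory.mktemp("long")
    spec = GeneratorSpec(
        n_templates=1_000,
        paired=False,
        read_length=20_000,
        qname_style="uuid",
        seed=31,
        fraction_unmapped=0.02,
    )
    return _build(tmp, spec, "long.bam")


def _absent_qname(style: str, rng: random.Random, i: int) -> str:
    # Shaped like the real qnames so they fall *inside* the indexed key
    # range (exercising the bounded scan), but guaranteed no collision:
    # real illumina qnames end in digits, these end in "A<i>"; real uuids
    # are 36 chars, these are longer.
    if style == "illumina":
        return f"SIM100:7:HXSIMDSXY:3:1101:{rng.randrange(1000, 60000)}:A{i}"
    if style == "uuid":
        return f"{rng.randrange(16 ** 8):08x}-0000-absent-{i}"
    return f"{chr(ord('A') + i % 26)}{i}"


def pick_queries(
    build: BuiltBam, n_present: int, n_absent: int, seed: int, style: str = "illumina"
) -> List[str]:
    """A seeded mix of present and definitely-absent qnames, shuffled."""
    rng = random.Random(seed)
    present = rng.sample(build.qnames(), n_present)
    absent = [_absent_qname(style, rng, i) for i in range(n_absent)]
    queries = present + absent
    rng.shuffle(queries)
    return queries
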