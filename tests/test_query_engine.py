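"""Three-step search: top-index narrowing, bounded data scan, BAM fetch."""

from __future__ import annotations

import random

import pytest

from bamqname import (
    IndexCorruptionError,
    IndexEntry,
    IndexPair,
    MissingIndexError,
    VirtualOffset,
    brute_force_lookup,
    find_scan_start,
    load_top_index,
    query,
    sampling_interval,
    scan_data,
    write_entries,
)
from conftest import pick_queries


def _toy_top(qnames):
    return [
        IndexEntry(q, VirtualOffset.from_packed(1000 * (i + 1)))
        for i, q in enumerate(qnames)
    ]


class TestFindScanStart:
    """Step 1 on a [B, E, H] toy index: start strictly below the query.

    A sampled key equal to the query may point mid-way into that qname's
    run of duplicate entries, so the scan starts at the last sampled key
    sorting strictly below the query — except for the minimum key, whose
    pointer is the file start and therefore always safe.
    """

    top = _toy_top([b"B", b"E", b"H"])

    def test_exact_hit_starts_one_stride_earlier(self):
        assert find_scan_start(self.top, b"E") == self.top[0].pointer

    def test_between_keys_returns_floor(self):
        assert find_scan_start(self.top, b"F") == self.top[1].pointer

    def test_minimum_key_starts_at_file_start(self):
        assert find_scan_start(self.top, b"B") == self.top[0].pointer

    def test_below_minimum_is_absent(self):
        assert find_scan_start(self.top, b"A") is None

    def test_above_maximum_returns_last(self):
        assert find_scan_start(self.top, b"Z") == self.top[2].pointer

    def test_empty_top_is_absent(self):
        assert find_scan_start([], b"Q") is None


class TestLoadTopIndex:
    def test_loads_built_top(self, small_build):
        top = load_top_index(small_build.pair.top_path)
        assert len(top) == small_build.n_top
        keys = [e.sort_key for e in top]
        assert keys == sorted(keys)

    def test_empty_top_file(self, tmp_path):
        path = tmp_path / "top.bgz"
        write_entries(path, [])
        assert load_top_index(path) == []

    def test_unsorted_top_is_rejected(self, tmp_path):
        path = tmp_path / "tampered.bgz"
        write_entries(
            path,
            [
                IndexEntry(b"ZEBRA", VirtualOffset(0, 0)),
                IndexEntry(b"AARDVARK", VirtualOffset(0, 20)),
            ],
        )
        with pytest.raises(IndexCorruptionError, match="rebuild"):
            load_top_index(path)


class TestScanData:
    def test_matches_brute_force_over_data_file(self, small_build):
        """Step 2 finds exactly the pointers a full data-file scan finds."""
        from bamqname import read_entries_from

        all_entries = [e for e, _ in read_entries_from(small_build.pair.data_path)]
        by_qname = {}
        for e in all_entries:
            by_qname.setdefault(e.qname, []).append(e.pointer)

        top = load_top_index(small_build.pair.top_path)
        rng = random.Random(6)
        for q in rng.sample(sorted(by_qname), 40):
            start = find_scan_start(top, q)
            assert start is not None
            matches, _ = scan_data(small_build.pair.data_path, start, q)
            assert matches == by_qname[q]

    def test_absent_in_range_stops_early(self, small_build):
        top = load_top_index(small_build.pair.top_path)
        q = top[2].qname + b"~absent"  # sorts just above a real key
        start = find_scan_start(top, q)
        matches, scanned = scan_data(small_build.pair.data_path, start, q)
        assert matches == []
        assert scanned <= sampling_interval(small_build.n_entries) + 1

    def test_scan_count_bound_holds(self, small_build):
        """Per-query decoded entries <= ceil(sqrt(N)) + matches + 1."""
        k = sampling_interval(small_build.n_entries)
        queries = pick_queries(small_build, 60, 20, seed=13)
        for res in query(small_build.bam, small_build.pair, queries):
            assert res.scan_count <= k + len(res.offsets) + 1


class TestQuery:
    def test_letter_walkthrough(self, letters_build):
        """Worked example: searching 'E' among paired letter qnames A..H.

        The top index narrows to the last sampled key <= 'E'; the bounded
        data scan collects both entries for 'E'; the fetches return mate 1
        and mate 2 of that template.
        """
        (res,) = query(letters_build.bam, letters_build.pair, ["E"])
        assert res.found and len(res.records) == 2
        assert {r.query_name for r in res.records} == {"E"}
        flags = sorted(r.flag & 0xC0 for r in res.records)
        assert flags == [0x40, 0x80]  # one read1, one read2
        assert res.offsets == sorted(res.offsets)

    def test_results_partition_the_bam(self, small_build):
        """Querying every qname returns each BAM record exactly once."""
        results = query(small_build.bam, small_build.pair, small_build.qnames())
        returned = sorted(
            rec.to_string() for res in results for rec in res.records
        )
        import pysam

        with pysam.AlignmentFile(str(small_build.bam), "rb") as bam:
            expected = sorted(rec.to_string() for rec in bam.fetch(until_eof=True))
        assert returned == expected

    def test_agrees_with_brute_force_oracle(self, small_build):
        queries = pick_queries(small_build, 30, 10, seed=21)
        for res in query(small_build.bam, small_build.pair, queries):
            oracle = brute_force_lookup(small_build.bam, res.qname)
            assert [r.to_string() for r in res.records] == [
                r.to_string() for r in oracle
            ]

    def test_unknown_qname_yields_empty_result(self, small_build):
        results = query(small_build.bam, small_build.pair, ["NO:SUCH:READ"])
        assert len(results) == 1
        assert not results[0].found
        assert results[0].records == []

    def test_input_order_and_duplicates_preserved(self, small_build):
        qs = small_build.qnames()[:3]
        batch = [qs[2], qs[0], qs[2], "NOPE", qs[1]]
        results = query(small_build.bam, small_build.pair, batch)
        assert [r.qname.decode() for r in results] == batch
        assert [r.records[0].to_string() for r in (results[0], results[2])][0] == [
            r.records[0].to_string() for r in (results[0], results[2])
        ][1]

    def test_idempotent(self, letters_build):
        a = query(letters_build.bam, letters_build.pair, ["C", "A"])
        b = query(letters_build.bam, letters_build.pair, ["C", "A"])
        assert [
            [r.to_string() for r in res.records] for res in a
        ] == [[r.to_string() for r in res.records] for res in b]

    def test_missing_index_names_the_fix(self, tmp_path):
        from bamqname import GeneratorSpec, generate_bam

        bam = tmp_path / "noindex.bam"
        generate_bam(GeneratorSpec(n_templates=2, qname_style="letters"), bam)
        with pytest.raises(MissingIndexError, match="index"):
            query(bam, IndexPair.locate(bam), ["A"])
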