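import numpy as np
import pytest

from splidkit.alignio import AlignmentBlock
from splidkit.engine import (
    GapRun,
    Indel,
    SplidConfig,
    candidate_splids,
    code_splid,
    exclude_mutual_overlaps,
    extract_splids,
    find_gap_runs,
    find_loci,
    group_indels,
    strict_filter,
)

import oracles
from conftest import make_block, random_alignment


def block_of(rows: dict[str, str]) -> AlignmentBlock:
    return AlignmentBlock("x", tuple(rows), tuple(rows.values()))


class TestFindGapRuns:
    def test_shared_run(self):
        block = block_of({"a": "AC--GT", "b": "AC--GT", "c": "ACTTGT"})
        runs = find_gap_runs(block)
        assert [(r.taxon, r.cols) for r in runs] == [("a", (2, 4)), ("b", (2, 4))]

    def test_question_mark_delimits(self):
        block = block_of({"a": "??-AC"})
        assert [r.cols for r in find_gap_runs(block)] == [(2, 3)]

    def test_no_gaps(self):
        assert find_gap_runs(block_of({"a": "ACGT"})) == []

    def test_matches_charwise_scan(self, rng):
        for _ in range(100):
            block = random_alignment(rng)
            expected = oracles.scan_runs(dict(zip(block.taxa, block.rows)))
            got = {}
            for run in find_gap_runs(block):
                got.setdefault(run.cols, set()).add(run.taxon)
            assert got == expected


class TestGroupIndels:
    def test_grouping_by_endpoints(self):
        runs = [GapRun("a", (2, 4), "x"), GapRun("b", (2, 4), "x"),
                GapRun("c", (2, 5), "x")]
        indels = group_indels(runs)
        assert [(i.cols, set(i.taxa)) for i in indels] == [
            ((2, 4), {"a", "b"}), ((2, 5), {"c"})]

    def test_single_run(self):
        [indel] = group_indels([GapRun("a", (1, 3), "x")])
        assert indel.taxa == frozenset("a") and indel.size == 2

    def test_no_shared_five_prime_end(self):
        runs = [GapRun("a", (1, 3), "x"), GapRun("b", (2, 4), "x")]
        assert len(group_indels(runs)) == 2


class TestFindLoci:
    def test_overlap_chain(self):
        indels = group_indels([GapRun("a", (2, 4), "x"), GapRun("b", (3, 6), "x"),
                               GapRun("c", (9, 11), "x")])
        loci = find_loci(indels)
        assert [(l.span, len(l.indels)) for l in loci] == [((2, 6), 2), ((9, 11), 1)]

    def test_abutting_intervals_separate(self):
        indels = group_indels([GapRun("a", (2, 4), "x"), GapRun("b", (4, 6), "x")])
        assert len(find_loci(indels)) == 2

    def test_empty(self):
        assert find_loci([]) == []

    def test_matches_union_find_oracle(self, rng):
        for _ in range(100):
            block = random_alignment(rng)
            indels = group_indels(find_gap_runs(block))
            loci = find_loci(indels)
            expected = oracles._components([i.cols for i in indels])
            got = [sorted(i.cols for i in l.indels) for l in loci]
            assert sorted(got) == sorted(expected)


def mk_indel(start, end, taxa):
    return Indel((start, end), frozenset(taxa), "x")


class TestRules:
    def test_rule1_default(self):
        locus = find_loci([mk_indel(2, 4, "ab"), mk_indel(2, 5, "c"),
                           mk_indel(4, 7, "c"), mk_indel(6, 7, "ab")])[0]
        assert [i.cols for i in candidate_splids(locus, SplidConfig())] == [(2, 4)]

    def test_rule1_min_size_one(self):
        locus = find_loci([mk_indel(6, 7, "ab")])[0]
        assert candidate_splids(locus, SplidConfig(min_size=1)) == [mk_indel(6, 7, "ab")]

    def test_rule1_max_size(self):
        locus = find_loci([mk_indel(2, 5, "ab")])[0]
        assert candidate_splids(locus, SplidConfig(max_size=2)) == []

    def test_rule2_mutual_exclusion(self):
        candidates = [mk_indel(2, 5, "ab"), mk_indel(3, 6, "cd")]
        assert exclude_mutual_overlaps(candidates) == []

    def test_rule2_noncandidate_overlap_survives(self):
        assert exclude_mutual_overlaps([mk_indel(2, 5, "ab")]) == [mk_indel(2, 5, "ab")]

    def test_rule2_disjoint_kept(self):
        candidates = [mk_indel(2, 4, "ab"), mk_indel(5, 7, "cd")]
        assert exclude_mutual_overlaps(candidates) == candidates

    def test_rule3_strict_removes(self):
        locus = find_loci([mk_indel(2, 6, "ab"), mk_indel(3, 4, "cd")])[0]
        candidate = [mk_indel(2, 6, "ab")]
        assert strict_filter(candidate, locus) == []

    def test_rule3_single_taxon_trigger_ignored(self):
        locus = find_loci([mk_indel(2, 6, "ab"), mk_indel(3, 4, "c")])[0]
        candidate = [mk_indel(2, 6, "ab")]
        assert strict_filter(candidate, locus) == candidate

    def test_rule3_no_size_one_identity(self):
        locus = find_loci([mk_indel(2, 6, "ab"), mk_indel(3, 6, "cd")])[0]
        candidate = [mk_indel(2, 6, "ab")]
        assert strict_filter(candidate, locus) == candidate


class TestCodeSplid:
    def test_basic_coding(self):
        block = block_of({"a": "AC--GT", "b": "AC--GT", "c": "ACTTGT"})
        splid = code_splid(mk_indel(2, 4, "ab"), block, ["a", "b", "c", "g"])
        assert splid.presence == frozenset("ab")
        assert splid.absence == frozenset("c")
        assert splid.missing == frozenset("g")

    def test_superset_run_is_missing(self):
        block = block_of({"a": "A----T", "b": "AC--GT", "c": "ACCGGT"})
        splid = code_splid(mk_indel(2, 4, "b"), block, ["a", "b", "c"])
        assert splid.missing == frozenset("a")

    def test_no_missing_when_universe_covered(self):
        block = block_of({"a": "AC--GT", "b": "AC--GT", "c": "ACTTGT"})
        splid = code_splid(mk_indel(2, 4, "ab"), block, ["a", "b", "c"])
        assert splid.missing == frozenset()

    def test_n_codes_as_absence(self):
        block = block_of({"a": "AC--GT", "b": "AC--GT", "c": "ACNNGT"})
        splid = code_splid(mk_indel(2, 4, "ab"), block, ["a", "b", "c"])
        assert "c" in splid.absence

    def test_question_mark_codes_missing(self):
        block = block_of({"a": "AC--GT", "b": "AC--GT", "c": "AC?TGT"})
        splid = code_splid(mk_indel(2, 4, "ab"), block, ["a", "b", "c"])
        assert "c" in splid.missing


class TestCaptionFixture:
    def test_strict_outcomes(self, caption_alignment):
        splids, stats = extract_splids(caption_alignment, SplidConfig(mode="strict"))
        assert [(s.global_cols, set(s.presence)) for s in splids] == [
            ((5, 8), {"a", "b"}), ((8, 10), {"f", "g"})]
        assert stats.n_loci == 4

    def test_fuzzy_adds_one(self, caption_alignment):
        splids, _ = extract_splids(caption_alignment, SplidConfig(mode="fuzzy"))
        assert [(s.global_cols, set(s.presence)) for s in splids] == [
            ((5, 8), {"a", "b"}), ((8, 10), {"f", "g"}), ((22, 26), {"a", "b"})]
        fuzzy_extra = splids[-1]
        assert "g" in fuzzy_extra.missing  # absent taxon coded '?'
        assert fuzzy_extra.absence == frozenset("f")

    def test_all_residue_alignment(self):
        block = make_block("plain", {}, 12, ["a", "b", "c"])
        splids, stats = extract_splids(block)
        assert splids == [] and stats.n_splids == 0


class TestOracleEquivalence:
    @pytest.mark.parametrize("min_size,mode", [
        (1, "strict"), (1, "fuzzy"), (2, "strict"),
        (2, "fuzzy"), (3, "strict"), (3, "fuzzy"),
    ])
    def test_random_alignments(self, rng, min_size, mode):
        for _ in range(300):
            block = random_alignment(rng)
            config = SplidConfig(min_size=min_size, mode=mode)
            splids, _ = extract_splids(block, config)
            got = {
                (s.indel.cols[0], s.indel.cols[1],
                 s.presence, s.absence, s.missing)
                for s in splids
            }
            expected = oracles.extract(
                dict(zip(block.taxa, block.rows)),
                min_size=min_size, mode=mode, universe=list(block.taxa))
            assert got == expected


class TestProperties:
    def test_strict_subset_of_fuzzy(self, rng):
        for _ in range(200):
            block = random_alignment(rng)
            strict, _ = extract_splids(block, SplidConfig(mode="strict"))
            fuzzy, _ = extract_splids(block, SplidConfig(mode="fuzzy"))
            strict_keys = {(s.indel.cols, s.presence) for s in strict}
            fuzzy_keys = {(s.indel.cols, s.presence) for s in fuzzy}
            assert strict_keys <= fuzzy_keys

    def test_min_size_monotonic(self, rng):
        for _ in range(100):
            block = random_alignment(rng)
            counts = [
                len(extract_splids(block, SplidConfig(min_size=m))[0])
                for m in (1, 2, 3)
            ]
            assert counts[0] >= counts[1] >= counts[2]

    def test_max_size_monotonic(self, rng):
        for _ in range(100):
            block = random_alignment(rng)
            counts = [
                len(extract_splids(block, SplidConfig(max_size=m))[0])
                for m in (2, 3, None)
            ]
            assert counts[0] <= counts[1] <= counts[2]

    def test_taxon_order_invariance(self, rng):
        for _ in range(50):
            block = random_alignment(rng)
            order = rng.permutation(len(block.taxa))
            shuffled = AlignmentBlock(
                block.block_id,
                tuple(block.taxa[i] for i in order),
                tuple(block.rows[i] for i in order))
            s1, _ = extract_splids(block)
            s2, _ = extract_splids(shuffled)
            assert {s.split_key() for s in s1} == {s.split_key() for s in s2}

    def test_accepted_splids_disjoint_and_multi_taxon(self, rng):
        for _ in range(100):
            block = random_alignment(rng)
            splids, _ = extract_splids(block, SplidConfig(min_size=1))
            for s in splids:
                assert len(s.presence) >= 2
            intervals = sorted(s.indel.cols for s in splids)
            for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
                assert e1 <= s2
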