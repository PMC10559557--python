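"""Merge-engine tests: breakpoint-distance clustering, inversion
reciprocal-overlap merging, union semantics, and database novelty, each
checked against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svforge import (MergeConfig, cluster_calls, compare_to_database,
                     merge_callsets, merge_inversions, merge_loci,
                     reciprocal_overlap)

from conftest import make_locus, make_record


# ---------------------------------------------------------------------------
# independent oracle: all-pairs linkage + transitive closure (BFS)

def _linked(a, b, cfg):
    if (a.chrom, a.svtype, a.orientation, a.mei_family) != \
            (b.chrom, b.svtype, b.orientation, b.mei_family):
        return False
    if a.svtype == "INV":
        if (a.length <= cfg.size_split) != (b.length <= cfg.size_split):
            return False
        lo, hi = max(a.start, b.start), min(a.end, b.end)
        shared = hi - lo + 1
        if shared <= 0:
            return False
        ro = min(shared / (a.end - a.start + 1), shared / (b.end - b.start + 1))
        return ro > cfg.inv_overlap_fraction
    return (abs(a.start - b.start) <= cfg.breakpoint_distance
            and abs(a.end - b.end) <= cfg.breakpoint_distance)


def bruteforce_partition(records, cfg):
    n = len(records)
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if _linked(records[i], records[j], cfg):
                adj[i].append(j)
                adj[j].append(i)
    seen, parts = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], []
        seen.add(i)
        while stack:
            k = stack.pop()
            comp.append(k)
            for m in adj[k]:
                if m not in seen:
                    seen.add(m)
                    stack.append(m)
        parts.append(frozenset(comp))
    return frozenset(parts)


def partition_of(loci, records):
    index = {id(r): i for i, r in enumerate(records)}
    return frozenset(frozenset(index[id(m)] for m in l.members) for l in loci)


def random_instance(rng, n, chroms=("chr1", "chr2")):
    records = []
    for k in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        svtype = str(rng.choice(["DEL", "DUP", "INV", "MEI"]))
        start = int(rng.integers(1, 300_000))
        if svtype == "MEI":
            records.append(make_record(chrom, start, start, "MEI",
                                       caller=f"c{k % 4}", sample=f"s{k % 7}"))
        else:
            length = int(rng.integers(60, 5000))
            records.append(make_record(chrom, start, start + length - 1,
                                       svtype, caller=f"c{k % 4}",
                                       sample=f"s{k % 7}"))
    return records


class TestClusterCalls:
    def test_nearby_breakpoints_merge(self):
        a = make_record(start=1000, end=5000)
        b = make_record(start=1300, end=5300, caller="callerB")
        assert len(cluster_calls([a, b], MergeConfig())) == 1

    def test_distant_starts_stay_apart(self):
        a = make_record(start=1000, end=5000)
        b = make_record(start=2500, end=5300, caller="callerB")
        assert len(cluster_calls([a, b], MergeConfig())) == 2

    def test_mixed_chromosomes_rejected(self):
        recs = [make_record("chr1"), make_record("chr2")]
        with pytest.raises(ValueError, match="chromosome"):
            cluster_calls(recs, MergeConfig())

    def test_jittered_copies_recover_true_loci(self):
        rng = np.random.default_rng(42)
        cfg = MergeConfig()
        true_starts = [10_000 + 5_000 * i for i in range(5)]
        records = []
        for _ in range(50):
            s = true_starts[int(rng.integers(5))]
            j1, j2 = rng.integers(-400, 401, 2)
            records.append(make_record(start=s + j1, end=s + 2000 + j2))
        loci = cluster_calls(records, cfg)
        assert len(loci) == 5
        assert partition_of(loci, records) == bruteforce_partition(records, cfg)


class TestReciprocalOverlap:
    def test_inclusive_interval_arithmetic(self):
        assert reciprocal_overlap((1000, 2000), (1100, 2100)) == \
            pytest.approx(901 / 1001)

    def test_identity_and_disjoint(self):
        assert reciprocal_overlap((1000, 2000), (1000, 2000)) == 1.0
        assert reciprocal_overlap((1000, 2000), (3000, 4000)) == 0.0

    def test_inverted_interval_rejected(self):
        with pytest.raises(ValueError):
            reciprocal_overlap((2000, 1000), (1000, 2000))

    @settings(max_examples=50, derandomize=True)
    @given(s1=st.integers(1, 10**6), l1=st.integers(1, 10**5),
           s2=st.integers(1, 10**6), l2=st.integers(1, 10**5))
    def test_symmetric_and_bounded(self, s1, l1, s2, l2):
        a, b = (s1, s1 + l1), (s2, s2 + l2)
        ro = reciprocal_overlap(a, b)
        assert ro == reciprocal_overlap(b, a)
        assert 0.0 <= ro <= 1.0


class TestMergeInversions:
    def test_high_overlap_merges(self):
        a = make_record(start=1000, end=2000, svtype="INV")
        b = make_record(start=1100, end=2100, svtype="INV", caller="callerB")
        assert len(merge_inversions([a, b], MergeConfig())) == 1

    def test_low_overlap_stays_apart(self):
        a = make_record(start=1000, end=2000, svtype="INV")
        b = make_record(start=1700, end=2700, svtype="INV", caller="callerB")
        assert len(merge_inversions([a, b], MergeConfig())) == 2

    def test_size_strata_never_mix(self):
        # 50 kb inversion fully inside a 150 kb one: different strata
        small = make_record(start=100_000, end=149_999, svtype="INV")
        large = make_record(start=80_000, end=229_999, svtype="INV",
                            caller="callerB")
        loci = merge_inversions([small, large], MergeConfig())
        assert len(loci) == 2
        for l in loci:
            lens = {m.length <= 100_000 for m in l.members}
            assert len(lens) == 1


class TestUnionMerge:
    def test_multi_caller_support_recorded(self):
        recs = [make_record(start=1000 + 50 * i, end=3000 + 50 * i,
                            caller=f"c{i}") for i in range(4)]
        (locus,) = merge_callsets(recs)
        assert len(locus.caller_support) == 4

    def test_single_caller_call_retained(self):
        lone = make_record(start=500_000, end=501_000, caller="c3")
        shared = [make_record(start=1000, end=3000, caller=f"c{i}")
                  for i in range(2)]
        loci = merge_callsets(shared + [lone])
        assert len(loci) == 2
        assert any(l.caller_support == {"c3"} for l in loci)

    def test_conservation_and_idempotence(self, tiny_truth):
        from svforge.simulate import simulate_callsets
        truth, cfg = tiny_truth
        records = [r for recs in simulate_callsets(truth, cfg).values()
                   for r in recs]
        loci = merge_callsets(records)
        assert sum(len(l.members) for l in loci) == len(records)
        again = merge_loci(loci)
        assert partition_of(again, records) == partition_of(loci, records)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        records = random_instance(rng, 120)
        cfg = MergeConfig()
        ref = partition_of(merge_callsets(records, cfg), records)
        for _ in range(3):
            shuffled = list(records)
            rng.shuffle(shuffled)
            assert partition_of(merge_callsets(shuffled, cfg), records) == ref

    def test_exact_duplicates_collapsed(self):
        r = make_record()
        (locus,) = merge_callsets([r, r])
        assert len(locus.members) == 1

    def test_representative_is_lower_median(self):
        starts = [1000, 1100, 1300]
        recs = [make_record(start=s, end=s + 500, caller=f"c{i}")
                for i, s in enumerate(starts)]
        (locus,) = merge_callsets(recs)
        assert locus.rep_start == 1100          # lower median of 3
        recs.append(make_record(start=1200, end=1700, caller="c9"))
        (locus,) = merge_callsets(recs)
        assert locus.rep_start == 1100          # lower median of 4


class TestDatabaseNovelty:
    def test_identical_locus_is_known(self):
        locus = make_locus(start=1000, end=2000)
        ref = [make_record(start=1000, end=2000, caller="db", sample="db")]
        flags, counts = compare_to_database([locus], ref)
        assert flags == [False] and counts["DEL"] == 0

    def test_isolated_locus_is_novel(self):
        locus = make_locus(start=100_000, end=101_000)
        ref = [make_record(start=200_000, end=201_000)]
        flags, counts = compare_to_database([locus], ref)
        assert flags == [True] and counts["DEL"] == 1

    def test_partial_reference_matches_bruteforce_scan(self):
        rng = np.random.default_rng(11)
        cfg = MergeConfig()
        loci, ref = [], []
        for i in range(100):
            s = 10_000 + 20_000 * i
            length = int(rng.integers(500, 3000))
            loci.append(make_locus(f"L{i}", start=s, end=s + length - 1))
            if i < 60:       # hide 60 loci in the reference at >= 75% overlap
                shift = int(rng.integers(0, max(1, length // 10)))
                ref.append(make_record(start=s + shift, end=s + shift
                                       + length - 1, caller="db", sample="db"))
        flags, counts = compare_to_database(loci, ref, cfg)
        assert sum(flags) == 40 and counts["DEL"] == 40
        # brute-force all-pairs scan
        for locus, flag in zip(loci, flags):
            known = any(
                r.svtype == locus.svtype and reciprocal_overlap(
                    (locus.rep_start, locus.rep_end), r.span) >= 0.75
                for r in ref)
            assert flag == (not known)

    def test_empty_reference_all_novel(self):
        flags, _ = compare_to_database([make_locus()], [])
        assert flags == [True]
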