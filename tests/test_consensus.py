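"""Distance filtering, replicate consensus, specificity and categorisation."""

import itertools

import numpy as np
import pytest

from pchic.consensus import (
    build_captured_index,
    categorize_interaction,
    cell_type_specific,
    distance_summary,
    filter_min_distance,
    replicate_consensus,
    split_specific_shared,
)
from pchic.genome import BaitSet, GenomeLayout, TssCatalog, build_fragment_map
from pchic.records import Interaction
from tests.conftest import make_interaction


def brute_force_consensus(per_replicate, ext=1000, min_support=2):
    """All-pairs overlap graph + transitive closure via union-find."""
    records = []
    for label, recs in per_replicate.items():
        for r in recs:
            if r.is_cis:
                records.append((label, r))
    parent = list(range(len(records)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(records)), 2):
        (la, a), (lb, b) = records[i], records[j]
        if a.gene != b.gene:
            continue
        if a.other_start - ext < b.other_end + ext and b.other_start - ext < a.other_end + ext:
            parent[find(i)] = find(j)
    clusters = {}
    for i in range(len(records)):
        clusters.setdefault(find(i), []).append(records[i])
    out = set()
    for members in clusters.values():
        reps = {label for label, _ in members}
        if len(reps) < min_support:
            continue
        recs = [r for _, r in members]
        out.add(
            (
                recs[0].gene,
                min(r.other_start for r in recs),
                max(r.other_end for r in recs),
                tuple(sorted(reps)),
            )
        )
    return out


def random_replicates(rng, n_genes=5, n_records=12, n_replicates=3):
    per_rep = {}
    for r in range(1, n_replicates + 1):
        label = f"rep{r}"
        recs = []
        for _ in range(n_records):
            gene = f"G{rng.integers(n_genes)}"
            start = int(rng.integers(20_000, 120_000))
            recs.append(
                make_interaction(
                    gene=gene,
                    bait=(0, 1000),
                    other=(start, start + int(rng.integers(200, 800))),
                    replicate=label,
                )
            )
        per_rep[label] = recs
    return per_rep


class TestDistanceFilter:
    def test_threshold_boundary(self):
        just_under = make_interaction(bait=(0, 1000), other=(10_249, 10_749))  # midpoints 9,999 apart
        at_threshold = make_interaction(bait=(0, 1000), other=(10_250, 10_750))  # exactly 10,000
        assert filter_min_distance([just_under]) == []
        assert filter_min_distance([at_threshold]) == [at_threshold]

    def test_trans_records_dropped(self):
        rec = make_interaction(other_chrom="chr9")
        assert filter_min_distance([rec]) == []

    def test_matches_linear_scan_oracle(self, rng):
        recs = [
            make_interaction(bait=(0, 1000), other=(int(s), int(s) + 400))
            for s in rng.integers(1_000, 40_000, size=100)
        ]
        got = filter_min_distance(recs)
        expected = [r for r in recs if abs(500 - (r.other_start + r.other_end) / 2) >= 10_000]
        assert got == expected


class TestReplicateConsensus:
    def test_identical_in_two_replicates_kept(self):
        rec = make_interaction(other=(50_000, 50_400))
        per_rep = {
            "rep1": [rec],
            "rep2": [make_interaction(other=(50_000, 50_400), replicate="rep2")],
            "rep3": [],
        }
        (cons,) = replicate_consensus(per_rep)
        assert cons.replicates == ("rep1", "rep2")
        assert (cons.distal_start, cons.distal_end) == (50_000, 50_400)

    def test_gap_under_double_extension_matches(self):
        # distal fragments 1,500 bp apart: extended intervals overlap
        per_rep = {
            "rep1": [make_interaction(other=(50_000, 50_400))],
            "rep2": [make_interaction(other=(51_900, 52_300), replicate="rep2")],
        }
        (cons,) = replicate_consensus(per_rep)
        assert cons.support == 2
        assert (cons.distal_start, cons.distal_end) == (50_000, 52_300)

    def test_gap_beyond_double_extension_splits(self):
        per_rep = {
            "rep1": [make_interaction(other=(50_000, 50_400))],
            "rep2": [make_interaction(other=(52_500, 52_900), replicate="rep2")],
        }
        assert replicate_consensus(per_rep) == []

    def test_single_replicate_support_dropped(self):
        per_rep = {"rep1": [make_interaction()], "rep2": [], "rep3": []}
        assert replicate_consensus(per_rep) == []

    def test_matches_brute_force_oracle(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            per_rep = random_replicates(rng)
            got = {
                (c.gene, c.distal_start, c.distal_end, c.replicates)
                for c in replicate_consensus(per_rep)
            }
            assert got == brute_force_consensus(per_rep)

    def test_symmetric_in_replicate_order(self, rng):
        per_rep = random_replicates(rng)
        a = replicate_consensus(per_rep)
        relabeled = {"rep3": per_rep["rep1"], "rep1": per_rep["rep2"], "rep2": per_rep["rep3"]}
        b = replicate_consensus(relabeled)
        key = lambda c: (c.gene, c.distal_start, c.distal_end, c.support)
        assert sorted(map(key, a)) == sorted(map(key, b))

    def test_monotone_in_ext_and_support(self, rng):
        # a larger extension can merge two supported clusters (fewer rows),
        # but the genomic span covered by consensus output never shrinks
        per_rep = random_replicates(rng, n_records=20)

        small = replicate_consensus(per_rep, ext=500)
        large = replicate_consensus(per_rep, ext=2_000)
        for c in small:
            assert any(
                b.gene == c.gene and b.distal_start <= c.distal_start and c.distal_end <= b.distal_end
                for b in large
            )
        n2 = len(replicate_consensus(per_rep, min_support=2))
        n3 = len(replicate_consensus(per_rep, min_support=3))
        assert n3 <= n2

    def test_chain_merges_transitively(self):
        # a-b overlap and b-c overlap, a-c do not: all three merge
        per_rep = {
            "rep1": [make_interaction(other=(50_000, 50_200))],
            "rep2": [make_interaction(other=(51_500, 51_700), replicate="rep2")],
            "rep3": [make_interaction(other=(53_000, 53_200), replicate="rep3")],
        }
        (cons,) = replicate_consensus(per_rep)
        assert cons.replicates == ("rep1", "rep2", "rep3")


class TestCellTypeSpecific:
    def test_absent_from_other_type_is_specific(self):
        per_rep = {"rep1": [make_interaction()], "rep2": [make_interaction(replicate="rep2")]}
        (cons,) = replicate_consensus(per_rep)
        assert cell_type_specific([cons], {"rep1": [], "rep2": [], "rep3": []}) == [cons]

    def test_single_other_replicate_removes_specificity(self):
        per_rep = {"rep1": [make_interaction()], "rep2": [make_interaction(replicate="rep2")]}
        (cons,) = replicate_consensus(per_rep)
        b = {"rep1": [make_interaction(replicate="b1")], "rep2": [], "rep3": []}
        assert cell_type_specific([cons], b) == []

    def test_partition_matches_quadratic_oracle(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            per_a = random_replicates(rng)
            per_b = random_replicates(rng)
            cons = replicate_consensus(per_a)
            specific, shared = split_specific_shared(cons, per_b)
            b_records = [r for recs in per_b.values() for r in recs]
            expected_specific = [
                c
                for c in cons
                if not any(
                    r.gene == c.gene
                    and c.distal_start - 1000 < r.other_end + 1000
                    and r.other_start - 1000 < c.distal_end + 1000
                    for r in b_records
                )
            ]
            assert specific == expected_specific
            assert set(specific) | set(shared) == set(cons)
            assert not set(specific) & set(shared)


class TestCategorisation:
    @pytest.fixture()
    def captured(self):
        layout = GenomeLayout({"chr1": 200_000})
        fm = build_fragment_map(layout, {"chr1": list(range(500, 200_000, 500))})
        cat = TssCatalog(
            __import__("pandas").DataFrame(
                {
                    "gene": ["GA", "GB"],
                    "chrom": ["chr1", "chr1"],
                    "pos": [10_250, 100_250],
                    "strand": ["+", "+"],
                }
            )
        )
        baits = BaitSet({"GA": (20,), "GB": (200,)})  # [10000,10500), [100000,100500)
        return build_captured_index(baits, cat, fm)

    def test_distal_end_with_other_tss_is_promoter(self, captured):
        rec = make_interaction(gene="GA", other=(100_000, 100_500))
        assert categorize_interaction(rec, captured) == "P-promoter"

    def test_distal_end_in_bait_without_tss_is_proximal(self, captured):
        # GB's bait fragment but a sub-interval missing the TSS at 100,250
        rec = make_interaction(gene="GA", other=(100_300, 100_500))
        assert categorize_interaction(rec, captured) == "P-proximal"

    def test_distal_end_outside_capture_is_distal(self, captured):
        rec = make_interaction(gene="GA", other=(50_000, 50_500))
        assert categorize_interaction(rec, captured) == "P-distal"


class TestDistanceSummary:
    def test_worked_example(self):
        recs = [
            make_interaction(bait=(0, 0), other=(d, d)) for d in (10_000, 20_000, 90_000)
        ]
        out = distance_summary(recs)
        assert out == {"median": 20_000.0, "mean": 40_000.0}

    def test_single_element(self):
        (rec,) = [make_interaction(bait=(0, 0), other=(12_345, 12_345))]
        out = distance_summary([rec])
        assert out["median"] == out["mean"] == 12_345.0

    def test_matches_sort_oracle(self, rng):
        dists = rng.integers(10_000, 1_000_000, size=1001)
        recs = [make_interaction(bait=(0, 0), other=(int(d), int(d))) for d in dists]
        out = distance_summary(recs)
        s = np.sort(dists)
        assert out["median"] == float(s[len(s) // 2])
        assert out["mean"] == pytest.approx(float(dists.mean()))

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            distance_summary([])
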