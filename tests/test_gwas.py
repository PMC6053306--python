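"""LD expansion and SNP-to-target-gene linking."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pchic.genome import PromoterRegion, TssCatalog
from pchic.gwas import (
    HaplotypePanel,
    LdSnp,
    ld_expand,
    link_snps,
    link_summary,
    r_squared,
    skip_count,
)
from pchic.records import ConsensusInteraction


class TestRSquared:
    def test_self_ld_is_one(self, rng):
        a = rng.integers(0, 2, size=60)
        a[0], a[1] = 0, 1
        assert r_squared(a, a) == pytest.approx(1.0)

    def test_worked_haplotype_table(self):
        # haplotype counts AB=40, Ab=10, aB=10, ab=40 over H=100
        a = np.array([1] * 50 + [0] * 50)
        b = np.array([1] * 40 + [0] * 10 + [1] * 10 + [0] * 40)
        assert r_squared(a, b) == pytest.approx(0.36)

    def test_complemented_vector_unchanged(self, rng):
        a = rng.integers(0, 2, size=80)
        b = rng.integers(0, 2, size=80)
        a[:2] = [0, 1]
        b[:2] = [0, 1]
        assert r_squared(a, 1 - b) == pytest.approx(r_squared(a, b))

    def test_monomorphic_is_nan(self):
        assert np.isnan(r_squared(np.zeros(10), np.array([0, 1] * 5)))

    def test_equals_squared_pearson(self, rng):
        for _ in range(200):
            a = rng.integers(0, 2, size=50)
            b = rng.integers(0, 2, size=50)
            if a.min() == a.max() or b.min() == b.max():
                continue
            expected = np.corrcoef(a, b)[0, 1] ** 2
            assert r_squared(a, b) == pytest.approx(expected, abs=1e-12)


def _panel(positions, matrix, chrom="chr1"):
    variants = pd.DataFrame(
        {"snp": [f"v{i}" for i in range(len(positions))], "chrom": chrom, "pos": positions}
    )
    return HaplotypePanel(variants, np.asarray(matrix))


class TestLdExpand:
    def test_tag_alone_returns_tag(self, rng):
        hap = rng.integers(0, 2, size=(1, 40))
        hap[0, :2] = [0, 1]
        panel = _panel([1000], hap)
        tags = pd.DataFrame({"snp": ["v0"], "chrom": ["chr1"], "pos": [1000], "disease_class": ["arrhythmia"]})
        out = ld_expand(tags, panel)
        assert [(s.snp, s.r2) for s in out] == [("v0", 1.0)]

    def test_duplicated_column_perfect_ld(self, rng):
        row = rng.integers(0, 2, size=40)
        row[:2] = [0, 1]
        panel = _panel([1000, 2000], np.vstack([row, row]))
        tags = pd.DataFrame({"snp": ["v0"], "chrom": ["chr1"], "pos": [1000], "disease_class": ["hf"]})
        out = ld_expand(tags, panel)
        assert {(s.snp, round(s.r2, 9)) for s in out} == {("v0", 1.0), ("v1", 1.0)}

    def test_matches_brute_force_filter(self, rng):
        n_var, H = 20, 60
        hap = rng.integers(0, 2, size=(n_var, H))
        positions = sorted(rng.choice(np.arange(1_000, 200_000), size=n_var, replace=False))
        panel = _panel(positions, hap)
        tag_row = 7
        tags = pd.DataFrame(
            {"snp": [f"v{tag_row}"], "chrom": ["chr1"], "pos": [positions[tag_row]], "disease_class": ["mi"]}
        )
        out = {s.snp for s in ld_expand(tags, panel)}
        expected = {f"v{tag_row}"}
        for i in range(n_var):
            if i == tag_row or abs(positions[i] - positions[tag_row]) > 50_000:
                continue
            r2 = r_squared(hap[tag_row], hap[i])
            maf = min(hap[i].mean(), 1 - hap[i].mean())
            if r2 > 0.9 and maf >= 0.01:
                expected.add(f"v{i}")
        assert out == expected

    def test_zero_thresholds_return_all_polymorphic_in_window(self, rng):
        n_var = 15
        hap = rng.integers(0, 2, size=(n_var, 50))
        hap[:, 0] = 0
        hap[:, 1] = 1  # all polymorphic
        positions = [10_000 + i * 1_000 for i in range(n_var)]
        panel = _panel(positions, hap)
        tags = pd.DataFrame({"snp": ["v7"], "chrom": ["chr1"], "pos": [positions[7]], "disease_class": ["x"]})
        out = ld_expand(tags, panel, r2_min=0.0, maf_min=0.0)
        assert {s.snp for s in out} == {f"v{i}" for i in range(n_var)}

    def test_highest_r2_kept_across_tags(self, rng):
        row = rng.integers(0, 2, size=40)
        row[:2] = [0, 1]
        noisy = row.copy()
        noisy[2:6] = 1 - noisy[2:6]
        panel = _panel([1_000, 2_000, 3_000], np.vstack([row, row, noisy]))
        tags = pd.DataFrame(
            {
                "snp": ["v0", "v2"],
                "chrom": ["chr1", "chr1"],
                "pos": [1_000, 3_000],
                "disease_class": ["x", "x"],
            }
        )
        out = {s.snp: s.r2 for s in ld_expand(tags, panel, r2_min=0.0, maf_min=0.0)}
        assert out["v1"] == pytest.approx(1.0)  # via v0, not the noisy tag


def _region(gene="GT", start=100_000, end=101_000):
    return PromoterRegion((gene,), "chr1", start, end, "+")


def _cons(gene="GT", distal=(200_000, 200_400)):
    return ConsensusInteraction(gene, "chr1", 100_000, 101_000, distal[0], distal[1], ("rep1", "rep2"), (5.0, 5.0))


def _ldsnp(pos, snp="s1", disease="x"):
    return LdSnp(snp=snp, chrom="chr1", pos=pos, r2=1.0, maf=0.2, tag=snp, disease_class=disease)


@pytest.fixture()
def catalog():
    return TssCatalog(
        pd.DataFrame(
            {
                "gene": ["GT", "GA", "GB"],
                "chrom": ["chr1"] * 3,
                "pos": [100_500, 150_000, 180_000],
                "strand": ["+", "+", "-"],
            }
        )
    )


class TestLinkSnps:
    def test_snp_in_promoter_region_excluded(self, catalog):
        links = link_snps([_ldsnp(100_500)], [_cons()], [_region()], catalog)
        assert links == []

    def test_snp_within_extension_linked(self, catalog):
        # 800 bp outside the distal fragment: inside the 1 kb extension
        links = link_snps([_ldsnp(199_200)], [_cons()], [_region()], catalog)
        assert len(links) == 1 and links[0].gene == "GT"

    def test_snp_beyond_extension_not_linked(self, catalog):
        assert link_snps([_ldsnp(198_900)], [_cons()], [_region()], catalog) == []

    def test_raising_ext_never_loses_links(self, catalog, rng):
        snps = [_ldsnp(int(p), snp=f"s{i}") for i, p in enumerate(rng.integers(110_000, 300_000, 40))]
        small = link_snps(snps, [_cons()], [_region()], catalog, ext=500)
        large = link_snps(snps, [_cons()], [_region()], catalog, ext=2_000)
        assert {(l.snp, l.gene) for l in small} <= {(l.snp, l.gene) for l in large}

    def test_planted_snps_fully_recovered(self, bundle):
        """Tags planted inside CM loop anchors link back to the planted gene."""
        from pchic.simulate import consensus_for

        consensus = consensus_for(bundle, "CM")
        planted = bundle.tag_snps[bundle.tag_snps["planted_gene"] != ""]
        snps = [
            LdSnp(row.snp, row.chrom, int(row.pos), 1.0, 0.2, row.snp, row.disease_class)
            for row in planted.itertuples()
        ]
        links = link_snps(snps, consensus, bundle.promoter_regions, bundle.tss_catalog)
        linked = {(l.snp, l.gene) for l in links}
        recovered = 0
        for row in planted.itertuples():
            # the planted loop must have survived replicate dropout to be linkable
            if any(c.gene == row.planted_gene and c.distal_start - 1000 <= row.pos < c.distal_end + 1000 for c in consensus):
                assert (row.snp, row.planted_gene) in linked
                recovered += 1
        assert recovered > 0


class TestSkipCount:
    def test_no_intervening_tss(self, catalog):
        assert skip_count(120_000, _region(), catalog) == 0

    def test_two_intervening_genes(self, catalog):
        assert skip_count(200_000, _region(), catalog) == 2  # GA and GB TSSs between

    def test_target_gene_own_tss_not_counted(self):
        catalog = TssCatalog(
            pd.DataFrame(
                {
                    "gene": ["GT", "GT"],
                    "chrom": ["chr1", "chr1"],
                    "pos": [100_500, 150_000],
                    "strand": ["+", "+"],
                }
            )
        )
        assert skip_count(200_000, _region(), catalog) == 0

    def test_matches_linear_scan(self, catalog, rng):
        for pos in rng.integers(90_000, 250_000, size=50):
            pos = int(pos)
            region = _region()
            edge = region.start if abs(pos - region.start) <= abs(pos - region.end) else region.end
            lo, hi = min(pos, edge), max(pos, edge)
            expected = {
                g
                for g, p in [("GA", 150_000), ("GB", 180_000)]
                if lo < p < hi
            }
            assert skip_count(pos, region, catalog) == len(expected)


class TestLinkSummary:
    def test_single_link(self, catalog):
        links = link_snps([_ldsnp(199_200)], [_cons()], [_region()], catalog)
        out = link_summary(links)
        assert out["n_snps"] == out["n_genes"] == 1
        assert out["median_distance"] == out["mean_distance"] == links[0].distance

    def test_two_disjoint_snps(self, catalog):
        cons2 = _cons(gene="GA", distal=(250_000, 250_400))
        region2 = PromoterRegion(("GA",), "chr1", 149_000, 151_000, "+")
        links = link_snps(
            [_ldsnp(200_100, snp="s1"), _ldsnp(250_100, snp="s2")],
            [_cons(), cons2],
            [_region(), region2],
            catalog,
        )
        out = link_summary(links)
        assert out["n_genes"] >= 2 and out["n_snps"] == 2

    def test_matches_brute_force_tabulation(self, catalog, rng):
        snps = [_ldsnp(int(p), snp=f"s{i}") for i, p in enumerate(rng.integers(110_000, 300_000, 30))]
        cons = [_cons(), _cons(gene="GA", distal=(250_000, 250_400))]
        regions = [_region(), PromoterRegion(("GA",), "chr1", 149_000, 151_000, "+")]
        links = link_snps(snps, cons, regions, catalog)
        out = link_summary(links)
        assert out["n_links"] == len(links)
        gps = {}
        for l in links:
            gps.setdefault(l.snp, set()).add(l.gene)
        expected_hist = {}
        for v in gps.values():
            expected_hist[len(v)] = expected_hist.get(len(v), 0) + 1
        assert out["genes_per_snp"] == expected_hist
        assert out["median_distance"] == float(np.median([l.distance for l in links]))

    def test_empty_links_all_na(self):
        out = link_summary([])
        assert out["n_links"] == 0 and np.isnan(out["median_distance"])
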