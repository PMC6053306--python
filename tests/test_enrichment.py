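"""Randomized-background enrichment machinery and expression binning."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pchic.enrichment import (
    BackgroundSampler,
    FeatureIndex,
    binned_enrichment,
    distal_fragments,
    enrichment,
    expression_bin,
    peak_density_expression_corr,
    promoter_distal_peaks,
    specificity_matrix,
)
from pchic.genome import GenomeLayout, PromoterRegion, build_fragment_map
from pchic.records import ConsensusInteraction


def peaks_frame(intervals, chrom="chr1"):
    return pd.DataFrame(
        {"chrom": chrom, "start": [s for s, _ in intervals], "end": [e for _, e in intervals]}
    )


class TestBackgroundSampler:
    def test_forced_pool_returns_exactly_that_set(self, toy_fragment_map):
        fm = toy_fragment_map
        # exclude everything except fragments 0..2 of chr1
        exclude = [("chr1", 1_500, 100_000), ("chr2", 0, 50_000)]
        sampler = BackgroundSampler(fm, exclude, seed=5)
        draws = sampler.sample(3, 20)
        assert sorted(sampler.pool.tolist()) == [0, 1, 2]
        for it in draws:
            assert sorted(it.tolist()) == [0, 1, 2]

    def test_same_seed_identical_draws(self, toy_fragment_map):
        a = BackgroundSampler(toy_fragment_map, seed=9).sample(10, 5)
        b = BackgroundSampler(toy_fragment_map, seed=9).sample(10, 5)
        np.testing.assert_array_equal(a, b)

    def test_inclusion_frequency_matches_binomial(self):
        fm = build_fragment_map(GenomeLayout({"c": 10_000}), {"c": list(range(1000, 10_000, 1000))})
        sampler = BackgroundSampler(fm, seed=2)
        assert sampler.pool.size == 10
        draws = sampler.sample(3, 10_000)
        freq = np.bincount(draws.ravel(), minlength=10) / 10_000
        sd = np.sqrt(0.3 * 0.7 / 10_000)
        assert np.all(np.abs(freq - 0.3) < 3 * sd + 1e-9)

    def test_pool_smaller_than_draw_raises(self, toy_fragment_map):
        sampler = BackgroundSampler(toy_fragment_map, [("chr1", 0, 100_000), ("chr2", 0, 49_000)], seed=1)
        with pytest.raises(ValueError):
            sampler.sample(sampler.pool.size + 1, 1)


class TestEnrichment:
    def test_saturating_peaks_give_fold_one(self, toy_fragment_map):
        sampler = BackgroundSampler(toy_fragment_map, seed=3)
        peaks = pd.DataFrame(
            {"chrom": ["chr1", "chr2"], "start": [0, 0], "end": [100_000, 50_000]}
        )
        res = enrichment(np.arange(10), peaks, sampler, iterations=20)
        assert res.observed == 1.0 and res.null_mean == 1.0 and res.fold == 1.0

    def test_counting_two_of_four(self):
        fm = build_fragment_map(GenomeLayout({"c": 4_000}), {"c": [1000, 2000, 3000]})
        sampler = BackgroundSampler(fm, seed=1)
        peaks = peaks_frame([(100, 200), (2_100, 2_200)], chrom="c")
        res = enrichment(np.arange(4), peaks, sampler, iterations=10)
        assert res.observed == 0.5

    def test_random_features_give_null_fold(self):
        # peaks planted uniformly at random: fold ~ 1, |Z| small on average
        fm = build_fragment_map(
            GenomeLayout({"c": 2_000_000}), {"c": list(range(400, 2_000_000, 400))}
        )
        rng = np.random.default_rng(8)
        folds, zs = [], []
        for _ in range(20):
            with_peak = rng.random(fm.n_fragments("c")) < 0.1
            starts = fm.starts("c")[with_peak]
            peaks = peaks_frame(list(zip(starts, starts + 300)), chrom="c")
            frag_sample = rng.choice(len(fm), size=400, replace=False)
            sampler = BackgroundSampler(fm, seed=int(rng.integers(2**31)))
            res = enrichment(frag_sample, peaks, sampler, iterations=100)
            folds.append(res.fold)
            zs.append(res.z)
        assert abs(np.mean(folds) - 1.0) < 0.05
        assert np.mean(np.abs(zs) < 3) > 0.8

    def test_zero_spread_null_yields_nan_p(self, toy_fragment_map):
        sampler = BackgroundSampler(toy_fragment_map, seed=3)
        peaks = pd.DataFrame({"chrom": ["chr1", "chr2"], "start": [0, 0], "end": [100_000, 50_000]})
        res = enrichment(np.arange(5), peaks, sampler, iterations=10)
        assert np.isnan(res.p)


class TestExpressionBins:
    @pytest.mark.parametrize(
        "tpm,expected",
        [(0.0, 1), (0.5, 2), (3.0, 2), (3.01, 3), (25.0, 3), (150.0, 4), (151.0, 5)],
    )
    def test_bin_boundaries_right_closed(self, tpm, expected):
        assert expression_bin(tpm) == expected

    def test_negative_tpm_rejected(self):
        with pytest.raises(ValueError):
            expression_bin(-1.0)

    def test_binned_enrichment_partitions_genes(self, toy_fragment_map):
        fm = toy_fragment_map
        cons = [
            ConsensusInteraction(g, "chr1", 0, 500, 30_000 + i * 2_000, 30_400 + i * 2_000, ("rep1", "rep2"), (5.0, 5.0))
            for i, g in enumerate(["G1", "G2", "G3"])
        ]
        tpm = {"G1": 0.0, "G2": 10.0, "G3": 500.0}
        sampler = BackgroundSampler(fm, seed=1)
        peaks = peaks_frame([(30_000, 30_100)])
        res = binned_enrichment(tpm, cons, peaks, sampler, iterations=10)
        assert set(res) == {1, 3, 5}  # empty bins skipped


class TestSpecificityMatrix:
    def _sampler(self, fm):
        return BackgroundSampler(fm, seed=4)

    def test_identical_features_all_shared(self, toy_fragment_map):
        peaks = peaks_frame([(30_000, 30_400), (60_000, 60_400)])
        cons = [ConsensusInteraction("G", "chr1", 0, 500, 30_000, 30_400, ("rep1", "rep2"), (5.0, 5.0))]
        grid = specificity_matrix(
            {"A_specific": cons, "B_specific": [], "shared": cons},
            peaks,
            peaks.copy(),
            self._sampler(toy_fragment_map),
            iterations=10,
        )
        by_class = grid.groupby("feature_class")["fold"].apply(lambda s: s.notna().any())
        assert bool(by_class["shared"])
        assert not by_class["A_only"] and not by_class["B_only"]

    def test_disjoint_features_no_shared_row(self, toy_fragment_map):
        pa = peaks_frame([(30_000, 30_400)])
        pb = peaks_frame([(60_000, 60_400)])
        cons = [ConsensusInteraction("G", "chr1", 0, 500, 30_000, 30_400, ("rep1", "rep2"), (5.0, 5.0))]
        grid = specificity_matrix(
            {"A_specific": cons, "B_specific": [], "shared": []},
            pa,
            pb,
            self._sampler(toy_fragment_map),
            iterations=10,
        )
        shared_row = grid[grid["feature_class"] == "shared"]
        assert shared_row["fold"].isna().all()

    def test_cells_equal_independent_runs(self, toy_fragment_map):
        pa = peaks_frame([(30_000, 30_400), (40_000, 40_200)])
        pb = peaks_frame([(60_000, 60_400)])
        cons = [ConsensusInteraction("G", "chr1", 0, 500, 30_000, 30_400, ("rep1", "rep2"), (5.0, 5.0))]
        sampler = self._sampler(toy_fragment_map)
        grid = specificity_matrix(
            {"A_specific": cons, "B_specific": [], "shared": []}, pa, pb, sampler, iterations=25, seed=7
        )
        cell = grid[(grid["feature_class"] == "A_only") & (grid["interaction_class"] == "A_specific")]
        frags = distal_fragments(cons, toy_fragment_map)
        solo = enrichment(frags, pa, sampler, iterations=25, seed=7)  # pa is fully A-only here
        assert cell["fold"].iloc[0] == pytest.approx(solo.fold)


class TestPromoterDistalPeaks:
    def test_peaks_over_promoters_removed(self):
        peaks = peaks_frame([(100, 200), (5_000, 5_100)])
        regions = [PromoterRegion(("G",), "chr1", 0, 1_000, "+")]
        out = promoter_distal_peaks(peaks, regions)
        assert out["start"].tolist() == [5_000]


class TestPeakDensityCorrelation:
    def test_perfectly_monotone(self, tss_catalog):
        peaks = peaks_frame([(9_000 + i, 9_001 + i) for i in range(5)])  # near GA only
        tpm = {"GA": 50.0, "GB": 5.0, "GC": 1.0}
        # GA 5 peaks, GB 0, GC 0 -> not strictly monotone; craft counts instead
        peaks = pd.concat(
            [
                peaks_frame([(9_000 + 2 * i, 9_001 + 2 * i) for i in range(6)]),  # GA: 6
                peaks_frame([(59_000 + 2 * i, 59_001 + 2 * i) for i in range(3)]),  # GB: 3
            ]
        )
        rho, p = peak_density_expression_corr(tpm, peaks, tss_catalog, window=2_000)
        assert rho == 1.0

    def test_reversed_gives_minus_one(self, tss_catalog):
        peaks = pd.concat(
            [
                peaks_frame([(9_000 + 2 * i, 9_001 + 2 * i) for i in range(6)]),
                peaks_frame([(59_000 + 2 * i, 59_001 + 2 * i) for i in range(3)]),
            ]
        )
        tpm = {"GA": 1.0, "GB": 5.0, "GC": 50.0}
        rho, _ = peak_density_expression_corr(tpm, peaks, tss_catalog, window=2_000)
        assert rho == -1.0

    def test_matches_rank_formula_oracle(self, rng):
        # 20 genes on one chromosome, TSS windows far enough apart that each
        # gene's 300 kb window holds an independent, known peak count
        from pchic.genome import TssCatalog

        genes = [f"G{i}" for i in range(20)]
        positions = [1_000_000 + i * 700_000 for i in range(20)]
        catalog = TssCatalog(
            pd.DataFrame({"gene": genes, "chrom": "chr1", "pos": positions, "strand": "+"})
        )
        counts = rng.integers(0, 15, size=20)
        intervals = []
        for pos, k in zip(positions, counts):
            intervals += [(pos + 10 * j, pos + 10 * j + 5) for j in range(int(k))]
        peaks = peaks_frame(intervals)
        tpm = {g: float(v) for g, v in zip(genes, rng.random(20))}
        got, _ = peak_density_expression_corr(tpm, peaks, catalog)

        x = np.array([tpm[g] for g in genes])
        y = counts.astype(float)

        def ranks(v):
            order = np.argsort(v, kind="mergesort")
            r = np.empty(len(v))
            i = 0
            sv = v[order]
            pos = np.arange(1.0, len(v) + 1)
            while i < len(v):
                j = i
                while j + 1 < len(v) and sv[j + 1] == sv[i]:
                    j += 1
                r[order[i : j + 1]] = pos[i : j + 1].mean()
                i = j + 1
            return r

        rx, ry = ranks(x), ranks(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert got == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_gives_nan(self, tss_catalog):
        peaks = peaks_frame([(1, 2)])
        tpm = {"GA": 5.0, "GB": 5.0, "GC": 5.0}
        rho, p = peak_density_expression_corr(tpm, peaks, tss_catalog)
        assert np.isnan(rho) and np.isnan(p)


class TestPlantedRecovery:
    def test_fold_approaches_planted_ratio(self, bundle):
        """Peaks planted at anchors at 3x the background rate are recovered."""
        cfg = bundle.config
        assert cfg.peak_anchor_prob / cfg.peak_background_rate == pytest.approx(3.0)
        loops = bundle.truth_loops
        cm = loops[(loops["cells"] == "both") | (loops["cells"] == "CM")]
        frags = np.unique(cm["fragment"].to_numpy())
        sampler = BackgroundSampler(bundle.fragment_map, bundle.exclude_regions(), seed=21)
        peaks = promoter_distal_peaks(bundle.peaks["CM"], bundle.promoter_regions)
        res = enrichment(frags, peaks, sampler, iterations=100)
        # small genome: anchors are a non-trivial share of the pool and the
        # compartment weighting of background peaks is noisy with few
        # intervals, so only a loose band is expected here; the sharp
        # parameter-recovery check runs at 5000-promoter scale
        assert 2.0 < res.fold < 5.0
        assert res.z > 5
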