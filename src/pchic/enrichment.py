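"""Randomized-background enrichment of chromatin features at interacting fragments.

The observed quantity is the proportion of distinct promoter-interacting
(distal) restriction fragments that overlap at least one feature peak. The
null is built by drawing, per iteration, the same number of fragments
uniformly without replacement from a background pool that excludes captured
(promoter) regions and unmappable gaps — a "genome-wide" background. Fold
enrichment is observed / null mean; significance is a one-sided Z test in
the direction of the observed deviation.

Peaks overlapping the captured region must be removed upstream (see
:func:`promoter_distal_peaks`) so results are not driven by the strong peak
signal over promoters. Fragment-level (un-extended) distal intervals are
used throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import FragmentMap, PromoterRegion
from .records import ConsensusInteraction

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "BackgroundSampler",
    "FeatureIndex",
    "promoter_distal_peaks",
    "distal_fragments",
    "enrichment",
    "expression_bin",
    "binned_enrichment",
    "specificity_matrix",
    "peak_density_expression_corr",
    "EXPRESSION_BIN_EDGES",
]

# TPM bins: {0}, (0,3], (3,25], (25,150], (150,inf); right-closed boundaries
EXPRESSION_BIN_EDGES = (0.0, 3.0, 25.0, 150.0)


@dataclass(frozen=True)
class EnrichmentResult:
    """Outcome of one randomized-background enrichment comparison."""

    observed: float
    null_mean: float
    null_sd: float
    fold: float
    z: float
    p: float
    iterations: int
    seed: int
    n: int  # number of observed fragments (and per-iteration draw size)

    @staticmethod
    def from_null(observed: float, null: np.ndarray, seed: int, n: int) -> "EnrichmentResult":
        mean = float(np.mean(null))
        sd = float(np.std(null, ddof=0))
        fold = observed / mean if mean > 0 else np.inf if observed > 0 else 1.0
        if sd == 0:
            logger.warning("null distribution has zero spread; p reported as NaN")
            z, p = np.nan, np.nan
        else:
            z = (observed - mean) / sd
            p = float(stats.norm.sf(abs(z)))  # one-sided, direction of effect
        return EnrichmentResult(
            observed=float(observed),
            null_mean=mean,
            null_sd=sd,
            fold=float(fold),
            z=float(z),
            p=p,
            iterations=int(null.size),
            seed=seed,
            n=n,
        )


class FeatureIndex:
    """Merged per-chromosome peak intervals for O(log n) overlap queries."""

    def __init__(self, peaks: pd.DataFrame):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, grp in peaks.groupby("chrom", sort=False):
            ivals = sorted(zip(grp["start"].astype(int), grp["end"].astype(int)))
            merged: list[list[int]] = []
            for s, e in ivals:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[chrom] = np.array([m[0] for m in merged], dtype=np.int64)
            self._ends[chrom] = np.array([m[1] for m in merged], dtype=np.int64)

    def overlaps(self, chrom: str, start: np.ndarray, end: np.ndarray) -> np.ndarray:
        """Vectorised: does [start_i, end_i) overlap any merged peak by >= 1 bp."""
        ps = self._starts.get(chrom)
        if ps is None:
            return np.zeros(len(start), dtype=bool)
        pe = self._ends.get(chrom)
        i = np.searchsorted(pe, start, side="right")
        ok = i < ps.size
        out = np.zeros(len(start), dtype=bool)
        out[ok] = ps[i[ok]] < np.asarray(end)[ok]
        return out

    def count_in(self, chrom: str, start: int, end: int) -> int:
        """Number of merged peaks overlapping [start, end)."""
        ps = self._starts.get(chrom)
        if ps is None or end <= start:
            return 0
        pe = self._ends.get(chrom)
        lo = int(np.searchsorted(pe, start, side="right"))
        hi = int(np.searchsorted(ps, end, side="left"))
        return max(0, hi - lo)


def promoter_distal_peaks(peaks: pd.DataFrame, promoter_regions: Sequence[PromoterRegion]) -> pd.DataFrame:
    """Drop peaks overlapping any captured promoter region (>= 1 bp)."""
    regions = FeatureIndex(
        pd.DataFrame(
            {
                "chrom": [r.chrom for r in promoter_regions],
                "start": [r.start for r in promoter_regions],
                "end": [r.end for r in promoter_regions],
            }
        )
    )
    keep = []
    for chrom, grp in peaks.groupby("chrom", sort=False):
        hit = regions.overlaps(chrom, grp["start"].to_numpy(), grp["end"].to_numpy())
        keep.append(grp.loc[~hit])
    if not keep:
        return peaks.iloc[0:0]
    return pd.concat(keep).sort_values(["chrom", "start"]).reset_index(drop=True)


def distal_fragments(consensus: Iterable[ConsensusInteraction], fragment_map: FragmentMap) -> np.ndarray:
    """Distinct global fragment indices covered by consensus distal intervals."""
    idx: set[int] = set()
    for it in consensus:
        idx.update(int(i) for i in fragment_map.overlapping(it.chrom, it.distal_start, it.distal_end))
    return np.array(sorted(idx), dtype=np.int64)


class BackgroundSampler:
    """Uniform without-replacement sampler over eligible background fragments.

    The eligible pool excludes fragments overlapping captured (promoter)
    regions and unmappable gap regions. Draws are reproducible given the
    seed; each iteration is an independent draw.
    """

    def __init__(
        self,
        fragment_map: FragmentMap,
        exclude_regions: Iterable[tuple[str, int, int]] = (),
        *,
        seed: int = 1,
    ):
        self.fragment_map = fragment_map
        self.seed = seed
        excluded: set[int] = set()
        for chrom, start, end in exclude_regions:
            excluded.update(int(i) for i in fragment_map.overlapping(chrom, start, end))
        pool = np.array([i for i in range(len(fragment_map)) if i not in excluded], dtype=np.int64)
        self.pool = pool

    def fragment_overlap_flags(self, features: FeatureIndex) -> np.ndarray:
        """Boolean flag per pool fragment: overlaps >= 1 feature peak."""
        flags = np.zeros(self.pool.size, dtype=bool)
        fm = self.fragment_map
        for chrom in fm.chromosomes:
            lo, hi = fm.index_range(chrom)
            mask = (self.pool >= lo) & (self.pool < hi)
            local = self.pool[mask] - lo
            flags[mask] = features.overlaps(chrom, fm.starts(chrom)[local], fm.ends(chrom)[local])
        return flags

    def sample(self, n: int, iterations: int, seed: int | None = None) -> np.ndarray:
        """(iterations, n) array of global fragment indices."""
        if n > self.pool.size:
            raise ValueError(f"background pool ({self.pool.size}) smaller than draw size {n}")
        rng = np.random.default_rng(self.seed if seed is None else seed)
        out = np.empty((iterations, n), dtype=np.int64)
        for it in range(iterations):
            out[it] = rng.choice(self.pool, size=n, replace=False)
        return out

    def null_proportions(self, n: int, iterations: int, features: FeatureIndex, seed: int | None = None) -> np.ndarray:
        """Per-iteration proportion of sampled fragments overlapping a peak."""
        flags = self.fragment_overlap_flags(features)
        draws = self.sample(n, iterations, seed=seed)
        positions = np.searchsorted(self.pool, draws)
        return flags[positions].mean(axis=1)


def _observed_proportion(fragments: np.ndarray, fragment_map: FragmentMap, features: FeatureIndex) -> float:
    if fragments.size == 0:
        raise ValueError("no distal fragments to test")
    hits = 0
    fm = fragment_map
    for chrom in fm.chromosomes:
        lo, hi = fm.index_range(chrom)
        local = fragments[(fragments >= lo) & (fragments < hi)] - lo
        if local.size:
            hits += int(features.overlaps(chrom, fm.starts(chrom)[local], fm.ends(chrom)[local]).sum())
    return hits / fragments.size


def enrichment(
    distal_fragment_idx: np.ndarray,
    feature_peaks: pd.DataFrame,
    sampler: BackgroundSampler,
    *,
    iterations: int = 100,
    seed: int | None = None,
) -> EnrichmentResult:
    """Fold enrichment of distal fragments overlapping a feature vs random fragments."""
    features = FeatureIndex(feature_peaks)
    fragments = np.unique(np.asarray(distal_fragment_idx, dtype=np.int64))
    observed = _observed_proportion(fragments, sampler.fragment_map, features)
    null = sampler.null_proportions(fragments.size, iterations, features, seed=seed)
    return EnrichmentResult.from_null(observed, null, seed=sampler.seed if seed is None else seed, n=fragments.size)


def expression_bin(tpm: float) -> int:
    """Expression bin 1..5 for a mean TPM value.

    Bin 1 is exactly zero; bins 2-4 are right-closed intervals (0,3], (3,25],
    (25,150]; bin 5 is everything above 150.
    """
    if tpm < 0:
        raise ValueError("TPM must be non-negative")
    if tpm == 0:
        return 1
    for b, edge in enumerate(EXPRESSION_BIN_EDGES[1:], start=2):
        if tpm <= edge:
            return b
    return 5


def binned_enrichment(
    tpm_by_gene: Mapping[str, float],
    consensus: Sequence[ConsensusInteraction],
    feature_peaks: pd.DataFrame,
    sampler: BackgroundSampler,
    *,
    iterations: int = 100,
    seed: int | None = None,
) -> dict[int, EnrichmentResult]:
    """Per-expression-bin enrichment of each bin's distal fragments.

    ``tpm_by_gene`` holds the mean TPM over replicates; genes without an
    expression value are skipped, as are empty bins (with a warning).
    """
    by_bin: dict[int, list[ConsensusInteraction]] = {b: [] for b in range(1, 6)}
    for it in consensus:
        tpm = tpm_by_gene.get(it.gene)
        if tpm is None:
            continue
        by_bin[expression_bin(float(tpm))].append(it)
    results: dict[int, EnrichmentResult] = {}
    for b in range(1, 6):
        frags = distal_fragments(by_bin[b], sampler.fragment_map)
        if frags.size == 0:
            logger.warning("expression bin %d is empty; skipped", b)
            continue
        results[b] = enrichment(frags, feature_peaks, sampler, iterations=iterations, seed=seed)
    return results


def _partition_peaks(peaks_a: pd.DataFrame, peaks_b: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(A-only, B-only, shared) peak sets; shared = overlaps the other cell type."""
    ix_b = FeatureIndex(peaks_b)
    ix_a = FeatureIndex(peaks_a)

    def split(peaks: pd.DataFrame, other: FeatureIndex) -> tuple[pd.DataFrame, pd.DataFrame]:
        hit_parts, only_parts = [], []
        for chrom, grp in peaks.groupby("chrom", sort=False):
            hit = other.overlaps(chrom, grp["start"].to_numpy(), grp["end"].to_numpy())
            hit_parts.append(grp.loc[hit])
            only_parts.append(grp.loc[~hit])
        empty = peaks.iloc[0:0]
        return (
            pd.concat(only_parts) if only_parts else empty,
            pd.concat(hit_parts) if hit_parts else empty,
        )

    a_only, a_shared = split(peaks_a, ix_b)
    b_only, b_shared = split(peaks_b, ix_a)
    shared = pd.concat([a_shared, b_shared]).sort_values(["chrom", "start"]).reset_index(drop=True)
    return a_only.reset_index(drop=True), b_only.reset_index(drop=True), shared


def specificity_matrix(
    interactions_by_class: Mapping[str, Sequence[ConsensusInteraction]],
    peaks_a: pd.DataFrame,
    peaks_b: pd.DataFrame,
    sampler: BackgroundSampler,
    *,
    iterations: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """3x3 fold-enrichment grid: feature classes (rows) x interaction classes.

    ``interactions_by_class`` keys are ``A_specific``, ``B_specific`` and
    ``shared``; feature rows are ``A_only``, ``B_only`` and ``shared`` (a
    peak is shared when it overlaps any peak of the other cell type by
    >= 1 bp). Each cell carries its own matched background run.
    """
    a_only, b_only, shared_peaks = _partition_peaks(peaks_a, peaks_b)
    feature_rows = {"A_only": a_only, "B_only": b_only, "shared": shared_peaks}
    records = []
    for feat_name, feat_peaks in feature_rows.items():
        for int_name, ints in interactions_by_class.items():
            frags = distal_fragments(ints, sampler.fragment_map)
            if feat_peaks.empty or frags.size == 0:
                records.append((feat_name, int_name, np.nan, np.nan, np.nan, np.nan))
                continue
            res = enrichment(frags, feat_peaks, sampler, iterations=iterations, seed=seed)
            records.append((feat_name, int_name, res.fold, res.observed, res.z, res.p))
    return pd.DataFrame(records, columns=["feature_class", "interaction_class", "fold", "observed", "z", "p"])


def peak_density_expression_corr(
    tpm_by_gene: Mapping[str, float],
    peaks: pd.DataFrame,
    tss_catalog,
    *,
    window: int = 300_000,
    genes_with_interaction: set[str] | None = None,
) -> tuple[float, float]:
    """Spearman correlation between expression and peak density near the TSS.

    Counts peaks within ``window`` of each gene's TSS and correlates the
    counts with mean TPM, restricted to genes with at least one significant
    interaction when ``genes_with_interaction`` is given. Returns (rho, p);
    (nan, nan) when either vector is constant.
    """
    index = FeatureIndex(peaks)
    tpms, counts = [], []
    for gene, tpm in tpm_by_gene.items():
        if genes_with_interaction is not None and gene not in genes_with_interaction:
            continue
        try:
            chrom, pos, _ = tss_catalog.tss_of(gene)
        except KeyError:
            continue
        tpms.append(float(tpm))
        counts.append(index.count_in(chrom, pos - window, pos + window))
    if len(tpms) < 3:
        raise ValueError("need at least 3 genes for a rank correlation")
    if len(set(tpms)) == 1 or len(set(counts)) == 1:
        logger.warning("constant vector; Spearman correlation undefined")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(tpms, counts)
    return float(rho), float(p)
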