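"""Resampling and permutation statistics for locus and gene sets.

Three randomized tests live here:

* the eQTL-loop enrichment with a promoter-remapping null: each promoter's
  set of interactions is re-assigned, as a block, to a different promoter on
  the same chromosome (a derangement), preserving each interaction's
  distance and strand orientation relative to its TSS;
* a gene-set resampling enrichment (phenotype-annotation style): the
  observed annotated fraction of a target gene set against draws of the
  same size from the eligible gene pool;
* hypergeometric term enrichment over a DAG-structured annotation (GO
  style), with annotations propagated to all parent terms before counting
  and Benjamini-Hochberg FDR control across tested terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .enrichment import EnrichmentResult
from .genome import TssCatalog
from .records import ConsensusInteraction

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationResult",
    "GoTermResult",
    "filter_promoter_distal_eqtls",
    "eqtl_loop_enrichment",
    "geneset_resample_enrichment",
    "go_enrichment",
    "bh_adjust",
]


@dataclass(frozen=True)
class PermutationResult:
    """Observed proportion against a permutation null distribution."""

    observed: float
    permuted: np.ndarray
    z: float
    p: float  # one-sided normal-tail p from permuted mean/sd
    p_empirical: float  # (rank of observed among permuted + 1) / (n_perm + 1)
    seed: int

    @property
    def n_perm(self) -> int:
        return int(self.permuted.size)

    @staticmethod
    def from_permutations(observed: float, permuted: np.ndarray, seed: int) -> "PermutationResult":
        permuted = np.asarray(permuted, dtype=float)
        mean = permuted.mean()
        sd = permuted.std(ddof=0)
        if sd == 0:
            logger.warning("permutation null has zero spread; Z/p reported as NaN")
            z, p = np.nan, np.nan
        else:
            z = (observed - mean) / sd
            p = float(stats.norm.sf(abs(z)))
        n_as_extreme = int(np.sum(permuted >= observed)) if observed >= mean else int(np.sum(permuted <= observed))
        p_emp = (n_as_extreme + 1) / (permuted.size + 1)
        return PermutationResult(float(observed), permuted, float(z), p, float(p_emp), seed)


def filter_promoter_distal_eqtls(
    eqtls: pd.DataFrame,
    tss_catalog: TssCatalog,
    promoter_regions,
    *,
    min_bp: int = 10_000,
) -> pd.DataFrame:
    """Keep eQTLs promoter-distal and >= ``min_bp`` from their gene's TSS."""
    region_bounds: dict[str, list[tuple[int, int]]] = {}
    for r in promoter_regions:
        region_bounds.setdefault(r.chrom, []).append((r.start, r.end))
    for c in region_bounds:
        region_bounds[c].sort()

    keep = []
    for row in eqtls.itertuples():
        try:
            chrom, tss, _ = tss_catalog.tss_of(row.gene)
        except KeyError:
            continue
        if row.chrom != chrom or abs(row.pos - tss) < min_bp:
            continue
        in_promoter = any(s <= row.pos < e for s, e in region_bounds.get(row.chrom, ()))
        if in_promoter:
            continue
        keep.append(row.Index)
    return eqtls.loc[keep].reset_index(drop=True)


def _signed_offsets(
    consensus: Sequence[ConsensusInteraction], tss_catalog: TssCatalog
) -> dict[str, dict[str, list[tuple[int, int]]]]:
    """chrom -> gene -> list of strand-aware (lo, hi) offsets from the TSS.

    Offsets are expressed in the gene's own orientation: for a + gene the
    offset of interval [s, e) is (s - tss, e - tss); for a − gene it is
    mirrored, so "upstream" stays upstream after re-mapping.
    """
    out: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for it in consensus:
        chrom, tss, strand = tss_catalog.tss_of(it.gene)
        if strand == "+":
            off = (it.distal_start - tss, it.distal_end - tss)
        else:
            off = (tss - it.distal_end, tss - it.distal_start)
        out.setdefault(it.chrom, {}).setdefault(it.gene, []).append(off)
    return out


def _sample_derangement(n: int, rng: np.random.Generator, *, max_tries: int = 10_000) -> np.ndarray:
    """Uniform fixed-point-free permutation of range(n), by rejection."""
    if n < 2:
        raise ValueError(
            "no derangement exists for a single promoter; at least two promoters "
            "per chromosome are required for the re-mapping null"
        )
    for _ in range(max_tries):
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm
    raise RuntimeError("failed to sample a derangement")  # pragma: no cover


def _overlap_proportion(
    eq_pos: np.ndarray,
    eq_gene: np.ndarray,
    int_lo: np.ndarray,
    int_hi: np.ndarray,
    int_gene: np.ndarray,
) -> tuple[int, int]:
    """(n eQTLs hitting an own-gene interval, n eQTLs hitting any interval)."""
    if int_lo.size == 0 or eq_pos.size == 0:
        return 0, 0
    inside = (eq_pos[:, None] >= int_lo[None, :]) & (eq_pos[:, None] < int_hi[None, :])
    any_hit = inside.any(axis=1)
    own_hit = (inside & (eq_gene[:, None] == int_gene[None, :])).any(axis=1)
    return int(own_hit.sum()), int(any_hit.sum())


def eqtl_loop_enrichment(
    eqtls: pd.DataFrame,
    consensus: Sequence[ConsensusInteraction],
    tss_catalog: TssCatalog,
    layout,
    *,
    n_perm: int = 1000,
    seed: int = 1,
    method: str = "derangement",
) -> PermutationResult:
    """Do eQTLs loop to their associated gene more often than chance?

    Observed: among eQTLs overlapping at least one promoter-distal consensus
    interval (fragment-level, un-extended), the fraction overlapping an
    interval whose interaction's gene equals the eQTL's associated gene.

    Null: per chromosome, each promoter's whole interaction set is re-mapped
    to a different promoter, keeping every interval's distance and strand
    orientation relative to the TSS; re-mapped intervals falling outside the
    chromosome are dropped and the proportion recomputed. ``method`` is
    ``"derangement"`` (uniform fixed-point-free permutation, the default) or
    ``"independent"`` (each promoter independently redrawn among the others).

    ``eqtls`` must already satisfy the promoter-distal / >= 10 kb filter
    (see :func:`filter_promoter_distal_eqtls`).
    """
    rng = np.random.default_rng(seed)
    offsets = _signed_offsets(consensus, tss_catalog)

    eq_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in eqtls.groupby("chrom", sort=False):
        eq_by_chrom[chrom] = (
            grp["pos"].to_numpy(dtype=np.int64),
            grp["gene"].to_numpy(dtype=object),
        )

    # frozen per-chromosome structures for fast permutation passes
    chrom_data = []
    for chrom, by_gene in sorted(offsets.items()):
        genes = sorted(by_gene)
        if chrom not in eq_by_chrom:
            continue
        tss = np.array([tss_catalog.tss_of(g)[1] for g in genes], dtype=np.int64)
        strand = np.array([1 if tss_catalog.tss_of(g)[2] == "+" else -1 for g in genes], dtype=np.int64)
        promoter_of_int, off_lo, off_hi = [], [], []
        for gi, g in enumerate(genes):
            for lo, hi in by_gene[g]:
                promoter_of_int.append(gi)
                off_lo.append(lo)
                off_hi.append(hi)
        chrom_data.append(
            dict(
                chrom=chrom,
                genes=np.array(genes, dtype=object),
                tss=tss,
                strand=strand,
                promoter_of_int=np.array(promoter_of_int, dtype=np.int64),
                off_lo=np.array(off_lo, dtype=np.int64),
                off_hi=np.array(off_hi, dtype=np.int64),
                length=int(layout[chrom]),
                eq_pos=eq_by_chrom[chrom][0],
                eq_gene=eq_by_chrom[chrom][1],
            )
        )

    def place(cd, assignment: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Interval coordinates given promoter index assignment per promoter."""
        tgt = assignment[cd["promoter_of_int"]]
        t_tss = cd["tss"][tgt]
        t_strand = cd["strand"][tgt]
        lo = np.where(t_strand == 1, t_tss + cd["off_lo"], t_tss - cd["off_hi"])
        hi = np.where(t_strand == 1, t_tss + cd["off_hi"], t_tss - cd["off_lo"])
        ok = (lo >= 0) & (hi <= cd["length"])
        return lo[ok], hi[ok], cd["genes"][tgt[ok]]

    identity_hits = [place(cd, np.arange(len(cd["genes"]))) for cd in chrom_data]
    own = sum(
        _overlap_proportion(cd["eq_pos"], cd["eq_gene"], lo, hi, g)[0]
        for cd, (lo, hi, g) in zip(chrom_data, identity_hits)
    )
    denom = sum(
        _overlap_proportion(cd["eq_pos"], cd["eq_gene"], lo, hi, g)[1]
        for cd, (lo, hi, g) in zip(chrom_data, identity_hits)
    )
    if denom == 0:
        logger.warning("no eQTL overlaps any promoter-distal interaction; enrichment undefined")
        return PermutationResult(float("nan"), np.full(n_perm, np.nan), np.nan, np.nan, np.nan, seed)
    observed = own / denom

    permuted = np.empty(n_perm, dtype=float)
    for k in range(n_perm):
        own_k = denom_k = 0
        for cd in chrom_data:
            n = len(cd["genes"])
            if method == "derangement":
                perm = _sample_derangement(n, rng)
            elif method == "independent":
                if n < 2:
                    raise ValueError("at least two promoters per chromosome are required")
                shift = rng.integers(1, n, size=n)
                perm = (np.arange(n) + shift) % n
            else:
                raise ValueError(f"unknown permutation method {method!r}")
            lo, hi, g = place(cd, perm)
            o, d = _overlap_proportion(cd["eq_pos"], cd["eq_gene"], lo, hi, g)
            own_k += o
            denom_k += d
        # a permutation where no eQTL overlaps any interval contributes 0:
        # no eQTL maps to an own-gene interaction there
        permuted[k] = own_k / denom_k if denom_k else 0.0
    return PermutationResult.from_permutations(observed, permuted, seed)


def geneset_resample_enrichment(
    target_genes: Iterable[str],
    eligible_pool: Iterable[str],
    annotated_set: Iterable[str],
    *,
    n_iter: int = 1000,
    seed: int = 1,
) -> EnrichmentResult:
    """Enrichment of a target gene set for an annotation, by pool resampling.

    Observed: the fraction of target genes carrying the annotation. Null:
    ``n_iter`` draws of the same size, uniformly without replacement, from
    the eligible pool (e.g. all genes with at least one promoter-distal
    interaction). Fold, Z and a one-sided p follow the shared randomized-
    enrichment conventions.
    """
    targets = sorted(set(target_genes))
    pool = np.array(sorted(set(eligible_pool)), dtype=object)
    annotated = set(annotated_set)
    if not set(targets) <= set(pool.tolist()):
        raise ValueError("target genes must be a subset of the eligible pool")
    if len(targets) == 0 or pool.size < len(targets):
        raise ValueError("eligible pool smaller than the target set")
    observed = float(np.mean([g in annotated for g in targets]))
    flags = np.array([g in annotated for g in pool], dtype=bool)
    rng = np.random.default_rng(seed)
    null = np.empty(n_iter, dtype=float)
    for k in range(n_iter):
        null[k] = flags[rng.choice(pool.size, size=len(targets), replace=False)].mean()
    return EnrichmentResult.from_null(observed, null, seed=seed, n=len(targets))


@dataclass(frozen=True)
class GoTermResult:
    """Hypergeometric enrichment of one ontology term."""

    term: str
    name: str
    universe_size: int
    annotated_in_universe: int
    set_size: int
    annotated_in_set: int
    p: float
    q: float


def propagate_annotations(
    associations: Mapping[str, set[str]], dag: nx.MultiDiGraph
) -> dict[str, set[str]]:
    """Extend each gene's terms with all ancestor (parent) terms in the DAG.

    Edges in the ontology graph run child -> parent, so graph descendants of
    a term are its ontological ancestors.
    """
    ancestors_cache: dict[str, set[str]] = {}
    out: dict[str, set[str]] = {}
    for gene, terms in associations.items():
        full = set(terms)
        for t in terms:
            if t not in ancestors_cache:
                ancestors_cache[t] = nx.descendants(dag, t) if t in dag else set()
            full |= ancestors_cache[t]
        out[gene] = full
    return out


def go_enrichment(
    gene_set: Iterable[str],
    universe: Iterable[str],
    dag: nx.MultiDiGraph,
    associations: Mapping[str, set[str]],
) -> list[GoTermResult]:
    """Upper-tail hypergeometric enrichment per term, BH-adjusted.

    Annotations are propagated to all parent terms before counting. For a
    term annotating K of N universe genes, with k of the n set genes
    annotated, p = P(X >= k) for X ~ Hypergeom(N, K, n). Terms with zero
    set hits are skipped.
    """
    genes = set(gene_set)
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    if not genes <= uni:
        raise ValueError("gene set must be a subset of the universe")
    full = propagate_annotations({g: t for g, t in associations.items() if g in uni}, dag)
    term_universe: dict[str, int] = {}
    term_set: dict[str, int] = {}
    for g, terms in full.items():
        for t in terms:
            term_universe[t] = term_universe.get(t, 0) + 1
            if g in genes:
                term_set[t] = term_set.get(t, 0) + 1
    n_uni, n_set = len(uni), len(genes)
    results = []
    for term in sorted(term_set):
        k = term_set[term]
        big_k = term_universe[term]
        p = float(stats.hypergeom.sf(k - 1, n_uni, big_k, n_set))
        name = dag.nodes[term].get("name", term) if term in dag else term
        results.append((term, name, big_k, k, p))
    if not results:
        return []
    qvals = bh_adjust([r[4] for r in results])
    return [
        GoTermResult(
            term=t,
            name=name,
            universe_size=n_uni,
            annotated_in_universe=big_k,
            set_size=n_set,
            annotated_in_set=k,
            p=p,
            q=float(q),
        )
        for (t, name, big_k, k, p), q in zip(results, qvals)
    ]


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
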