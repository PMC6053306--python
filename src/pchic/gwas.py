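"""LD expansion of GWAS tag SNPs and SNP-to-target-gene linking via loops.

A GWAS lead (tag) SNP proxies every variant in high linkage disequilibrium
with it. Each tag is expanded to all variants with r² > 0.9 within ±50 kb
and minor-allele frequency >= 0.01, computed on a phased haplotype panel.
LD SNPs residing in promoter-distal restriction fragments are then linked
to target genes through 1 kb-extended consensus interactions; SNPs inside
any captured promoter region are excluded first.

r² here is the standard composite measure D²/(p_A p_a p_B p_b), which for
0/1 haplotype indicator vectors equals the squared Pearson correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import FragmentMap, PromoterRegion, TssCatalog
from .records import ConsensusInteraction
from .tads import DomainSet

logger = logging.getLogger(__name__)

__all__ = [
    "HaplotypePanel",
    "LdSnp",
    "SnpGeneLink",
    "r_squared",
    "ld_expand",
    "link_snps",
    "skip_count",
    "link_summary",
]


class HaplotypePanel:
    """Phased biallelic haplotypes: variant metadata plus a 0/1 matrix.

    ``variants`` must have columns (snp, chrom, pos), pos 0-based;
    ``matrix`` is variants x haplotypes with alleles coded 0/1. Unphased
    genotype input is not supported: phase upstream or supply haplotypes.
    """

    def __init__(self, variants: pd.DataFrame, matrix: np.ndarray):
        required = {"snp", "chrom", "pos"}
        if not required <= set(variants.columns):
            raise ValueError(f"variant table needs columns {sorted(required)}")
        matrix = np.asarray(matrix)
        if not np.isin(matrix, (0, 1)).all():
            raise ValueError(
                "haplotype matrix must be 0/1 phased alleles; unphased genotype "
                "calls are not supported — phase the panel or supply haplotypes"
            )
        if matrix.shape[0] != len(variants):
            raise ValueError("variant table and haplotype matrix disagree in length")
        self.variants = variants.reset_index(drop=True)
        self.matrix = matrix.astype(np.int8)
        self._row_of = {s: i for i, s in enumerate(self.variants["snp"])}

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[1]

    def row_of(self, snp: str) -> int:
        return self._row_of[snp]

    def maf(self, row: int) -> float:
        f = float(self.matrix[row].mean())
        return min(f, 1.0 - f)


@dataclass(frozen=True)
class LdSnp:
    """A variant retained by LD expansion around a tag SNP."""

    snp: str
    chrom: str
    pos: int
    r2: float
    maf: float
    tag: str
    disease_class: str


@dataclass(frozen=True)
class SnpGeneLink:
    """An LD SNP linked to a target gene via a consensus interaction."""

    snp: str
    chrom: str
    pos: int
    gene: str
    distance: float  # |SNP - promoter-region midpoint|
    same_tad: bool | None
    skipped_tss: int
    disease_class: str
    interaction: ConsensusInteraction


def r_squared(alleles_a: np.ndarray, alleles_b: np.ndarray) -> float:
    """LD r² between two phased 0/1 allele vectors over the same haplotypes.

    r² = D² / (p_A p_a p_B p_b) with D = p_AB − p_A p_B. Symmetric, equal to
    the squared Pearson correlation of the indicator vectors, and invariant
    to swapping allele labels at either site. NaN when either variant is
    monomorphic.
    """
    a = np.asarray(alleles_a, dtype=float)
    b = np.asarray(alleles_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("haplotype vectors must have equal length")
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return float("nan")
    d = (a * b).mean() - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def ld_expand(
    tag_snps: pd.DataFrame,
    panel: HaplotypePanel,
    *,
    window: int = 50_000,
    r2_min: float = 0.9,
    maf_min: float = 0.01,
) -> list[LdSnp]:
    """Expand tag SNPs to all panel variants in high LD.

    ``tag_snps`` needs columns (snp, chrom, pos, disease_class). For each
    tag, variants within ±``window`` of the tag with r² > ``r2_min`` and
    MAF >= ``maf_min`` are retained; the tag itself is always kept (r² = 1).
    Within each disease class one record per SNP survives de-duplication,
    keeping the highest r². Tags absent from the panel are logged and
    skipped.
    """
    best: dict[tuple[str, str], LdSnp] = {}
    for tag in tag_snps.itertuples():
        if tag.snp not in panel._row_of:
            logger.warning("tag SNP %s absent from haplotype panel; skipped", tag.snp)
            continue
        trow = panel.row_of(tag.snp)
        tpos = int(panel.variants.at[trow, "pos"])
        tchrom = panel.variants.at[trow, "chrom"]
        in_window = panel.variants.index[
            (panel.variants["chrom"] == tchrom) & (panel.variants["pos"] - tpos).abs().le(window)
        ]
        tag_alleles = panel.matrix[trow]
        for row in in_window:
            snp = panel.variants.at[row, "snp"]
            if snp == tag.snp:
                r2 = 1.0
            else:
                r2 = r_squared(tag_alleles, panel.matrix[row])
                if not r2 > r2_min:
                    continue
                if panel.maf(row) < maf_min:
                    continue
            rec = LdSnp(
                snp=snp,
                chrom=tchrom,
                pos=int(panel.variants.at[row, "pos"]),
                r2=float(r2),
                maf=panel.maf(row),
                tag=tag.snp,
                disease_class=tag.disease_class,
            )
            key = (snp, tag.disease_class)
            if key not in best or rec.r2 > best[key].r2:
                best[key] = rec
    return sorted(best.values(), key=lambda s: (s.chrom, s.pos, s.disease_class, s.snp))


def _in_any_region(pos: int, regions: list[tuple[int, int]]) -> bool:
    for s, e in regions:
        if s <= pos < e:
            return True
        if s > pos:
            break
    return False


def skip_count(
    snp_pos: int,
    target_region: PromoterRegion,
    tss_catalog: TssCatalog,
    *,
    target_genes: set[str] | None = None,
) -> int:
    """Distinct non-target genes with a TSS strictly between SNP and promoter.

    The interval is the open stretch between the SNP position and the edge of
    the target promoter region nearest the SNP; the target gene's own TSSs
    never count.
    """
    edge = target_region.start if abs(snp_pos - target_region.start) <= abs(snp_pos - target_region.end) else target_region.end
    lo, hi = (snp_pos, edge) if snp_pos <= edge else (edge, snp_pos)
    exclude = target_genes if target_genes is not None else set(target_region.genes)
    # strictly-between: open interval (lo, hi)
    return len(tss_catalog.genes_in(target_region.chrom, lo + 1, hi, exclude=exclude))


def link_snps(
    ld_snps: Sequence[LdSnp],
    consensus: Sequence[ConsensusInteraction],
    promoter_regions: Sequence[PromoterRegion],
    tss_catalog: TssCatalog,
    *,
    ext: int = 1_000,
    domains: DomainSet | None = None,
) -> list[SnpGeneLink]:
    """Link promoter-distal LD SNPs to target genes via extended interactions.

    A SNP inside any captured promoter region is excluded entirely. A link
    exists when the SNP position falls within the 1 kb-extended distal
    interval of a consensus interaction; one link per (SNP, gene,
    disease class), keeping the closest interaction when several qualify.
    """
    region_by_gene = {g: r for r in promoter_regions for g in r.genes}
    regions_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in promoter_regions:
        regions_by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    for chrom in regions_by_chrom:
        regions_by_chrom[chrom].sort()

    ints_by_chrom: dict[str, list[ConsensusInteraction]] = {}
    for it in consensus:
        ints_by_chrom.setdefault(it.chrom, []).append(it)

    links: dict[tuple[str, str, str], SnpGeneLink] = {}
    for snp in ld_snps:
        if _in_any_region(snp.pos, regions_by_chrom.get(snp.chrom, [])):
            continue
        for it in ints_by_chrom.get(snp.chrom, ()):
            if not (it.distal_start - ext <= snp.pos < it.distal_end + ext):
                continue
            region = region_by_gene.get(it.gene)
            if region is None:
                region = PromoterRegion((it.gene,), it.chrom, it.promoter_start, it.promoter_end, "+")
            distance = abs(snp.pos - region.midpoint)
            same_tad = None
            if domains is not None:
                d_snp = domains.domain_containing(snp.chrom, snp.pos)
                d_gene = domains.domain_containing(region.chrom, region.midpoint)
                same_tad = d_snp is not None and d_snp == d_gene
            link = SnpGeneLink(
                snp=snp.snp,
                chrom=snp.chrom,
                pos=snp.pos,
                gene=it.gene,
                distance=distance,
                same_tad=same_tad,
                skipped_tss=skip_count(snp.pos, region, tss_catalog),
                disease_class=snp.disease_class,
                interaction=it,
            )
            key = (snp.snp, it.gene, snp.disease_class)
            if key not in links or link.distance < links[key].distance:
                links[key] = link
    return sorted(links.values(), key=lambda l: (l.chrom, l.pos, l.gene, l.disease_class))


def link_summary(links: Sequence[SnpGeneLink]) -> dict:
    """Headline statistics over a set of SNP-target gene links."""
    if not links:
        return {
            "n_links": 0,
            "n_snps": np.nan,
            "n_genes": np.nan,
            "median_distance": np.nan,
            "mean_distance": np.nan,
            "pct_same_tad": np.nan,
            "pct_skipping": np.nan,
            "genes_per_snp": {},
            "skip_counts": {},
        }
    pairs = {(l.snp, l.gene) for l in links}
    dist = np.array([l.distance for l in links], dtype=float)
    tad_flags = [l.same_tad for l in links if l.same_tad is not None]
    genes_per_snp: dict[str, set[str]] = {}
    for l in links:
        genes_per_snp.setdefault(l.snp, set()).add(l.gene)
    gps_counts: dict[int, int] = {}
    for g in genes_per_snp.values():
        gps_counts[len(g)] = gps_counts.get(len(g), 0) + 1
    skip_counts: dict[int, int] = {}
    for snp, gene in sorted(pairs):
        k = min(l.skipped_tss for l in links if l.snp == snp and l.gene == gene)
        skip_counts[k] = skip_counts.get(k, 0) + 1
    n_pairs = len(pairs)
    return {
        "n_links": len(links),
        "n_snps": len(genes_per_snp),
        "n_genes": len({l.gene for l in links}),
        "median_distance": float(np.median(dist)),
        "mean_distance": float(np.mean(dist)),
        "pct_same_tad": float(100.0 * np.mean(tad_flags)) if tad_flags else np.nan,
        "pct_skipping": 100.0 * sum(v for k, v in skip_counts.items() if k >= 1) / n_pairs,
        "genes_per_snp": dict(sorted(gps_counts.items())),
        "skip_counts": dict(sorted(skip_counts.items())),
    }
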