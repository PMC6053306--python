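"""Synthetic promoter-capture Hi-C datasets with planted, recoverable structure.

The generator emulates the inputs of every downstream stage at desk scale:
a restriction-fragment map with geometric cut spacing (mean 422 bp, the
MboI average), bait selection by the capture design rules, distance-decaying
true loops observed through three noisy replicates with dropout, ChIP-seq
peaks enriched at loop anchors over a background rate, TAD and compartment
tracks, an LD-structured haplotype panel with tag SNPs, eQTLs with a planted
preference for looping to their own gene, and expression coupled to
compartment and local peak density. Every planted object is recorded in
truth tables so pipeline outputs can be scored.

All randomness flows from a single seed; the same config yields a
byte-identical bundle.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .compartments import CompartmentTrack
from .consensus import filter_min_distance, replicate_consensus
from .genome import (
    BaitSet,
    FragmentMap,
    GenomeLayout,
    PromoterRegion,
    TssCatalog,
    build_fragment_map,
    merge_promoter_regions,
    select_bait_fragments,
)
from .gwas import HaplotypePanel
from .records import ConsensusInteraction, Interaction
from .tads import DomainSet

logger = logging.getLogger(__name__)

__all__ = ["SimConfig", "SimBundle", "simulate_dataset", "truth_report"]

CELL_TYPES = ("iPSC", "CM")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic dataset; defaults are the study conditions.

    Anchored values: 422 bp mean fragment size (MboI), 10 kb minimum loop
    span, 3 replicates, ~55% of loops shared between the two cell types.
    The remaining knobs are generator choices documented in the methods
    note.
    """

    seed: int = 1
    chrom_lengths: tuple[tuple[str, int], ...] = (("chr1", 6_000_000), ("chr2", 4_000_000))
    mean_fragment_bp: int = 422
    n_genes: int = 120
    tss_edge_margin: int = 100_000
    tss_min_spacing: int = 25_000
    loops_per_promoter: float = 6.0  # Poisson mean
    decay_alpha: float = 1.0
    min_span_bp: int = 10_000
    max_span_bp: int = 1_500_000
    # true loops are sampled this far above min_span so that replicate jitter
    # and promoter-midpoint offsets never push an observed span below the
    # 10 kb filter (which would bias recovery-rate checks)
    span_margin_bp: int = 3_000
    anchor_min_separation: int = 5_000  # between anchors of the same gene
    n_replicates: int = 3
    dropout: float = 0.2
    jitter_prob: float = 0.05
    noise_rate: float = 0.1  # noise loops per replicate, as fraction of true loops
    shared_fraction: float = 0.55
    peak_background_rate: float = 0.1  # beta, averaged over compartments
    peak_anchor_prob: float = 0.3  # pi_peak
    # background peaks are denser in active (A) chromatin; the two factors
    # average to 1 so the genome-wide background rate stays beta
    peak_compartment_factor_a: float = 1.6
    peak_compartment_factor_b: float = 0.4
    tad_median_bp: int = 640_000
    tad_sigma: float = 0.55
    boundary_bp: int = 40_000
    gap_prob: float = 0.1
    gap_bp: int = 120_000
    compartment_mean_bp: int = 500_000
    compartment_switch_prob: float = 0.15
    n_haplotypes: int = 100
    ld_block_bp: int = 50_000
    ld_mutation_rate: float = 0.02
    ld_variant_spacing: int = 2_000
    n_tag_snps: int = 12
    tag_in_anchor_frac: float = 0.6
    n_eqtls: int = 200
    eqtl_loop_preference: float = 0.5  # pi_eqtl
    expr_base_log2: float = 3.0
    expr_sd_log2: float = 2.0
    compartment_effect_log2: float = 1.5
    peak_density_effect_log2: float = 0.25
    expr_replicate_sd: float = 0.25
    expr_zero_prob: float = 0.15

    def validate(self, layout: GenomeLayout) -> None:
        for name, length in layout.lengths.items():
            if self.min_span_bp >= length:
                raise ValueError(f"min loop span exceeds chromosome {name!r} length")
        for rate in (
            self.dropout,
            self.jitter_prob,
            self.shared_fraction,
            self.peak_background_rate,
            self.peak_anchor_prob,
            self.compartment_switch_prob,
            self.ld_mutation_rate,
            self.tag_in_anchor_frac,
            self.eqtl_loop_preference,
            self.expr_zero_prob,
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {rate} outside [0, 1]")
        if self.decay_alpha <= 0:
            raise ValueError("distance-decay exponent must be positive")


@dataclass
class SimBundle:
    """All generated inputs plus truth tables."""

    config: SimConfig
    layout: GenomeLayout
    fragment_map: FragmentMap
    tss_catalog: TssCatalog
    baits: BaitSet
    promoter_regions: list[PromoterRegion]
    interactions: dict[str, dict[str, list[Interaction]]]  # cell type -> replicate -> records
    domains: dict[str, DomainSet]
    compartment_values: dict[str, pd.DataFrame]  # signed bedGraph frames
    peaks: dict[str, pd.DataFrame]
    gaps: pd.DataFrame  # unmappable regions (chrom, start, end)
    haplotype_panel: HaplotypePanel
    tag_snps: pd.DataFrame
    eqtls: pd.DataFrame
    expression: pd.DataFrame  # gene x (celltype_rep) TPM
    truth_loops: pd.DataFrame
    phenotype_genes: list[str] = field(default_factory=list)
    go_obo_text: str = ""
    gene_go: dict[str, set[str]] = field(default_factory=dict)
    truth: dict = field(default_factory=dict)

    def compartment_track(self, cell_type: str) -> CompartmentTrack:
        return CompartmentTrack.from_bedgraph(self.compartment_values[cell_type])

    def exclude_regions(self) -> list[tuple[str, int, int]]:
        """Captured promoter regions plus unmappable gaps (background exclusion)."""
        out = [(r.chrom, r.start, r.end) for r in self.promoter_regions]
        out += [(r.chrom, int(r.start), int(r.end)) for r in self.gaps.itertuples()]
        return out

    def mean_tpm(self, cell_type: str) -> dict[str, float]:
        cols = [c for c in self.expression.columns if c.startswith(cell_type + "_")]
        return self.expression[cols].mean(axis=1).to_dict()

    def write(self, outdir) -> None:
        """Emit the bundle as the pipeline's expected input files plus truth/."""
        out = Path(outdir)
        (out / "interactions").mkdir(parents=True, exist_ok=True)
        (out / "truth").mkdir(exist_ok=True)
        pio.write_fragment_map_bed(self.fragment_map, out / "fragments.bed")
        pio.write_tss_table(self.tss_catalog, out / "tss.tsv")
        bait_rows = [(g, i) for g, idx in sorted(self.baits.baits.items()) for i in idx]
        pio.write_table(pd.DataFrame(bait_rows, columns=["gene", "fragment_id"]), out / "baits.tsv")
        for ct, reps in self.interactions.items():
            for rep, records in reps.items():
                pio.write_interactions(records, out / "interactions" / f"{ct}_{rep}.ibed")
        for ct in CELL_TYPES:
            pio.write_bed(self.domains[ct].frame.rename(columns={"label": "name"}), out / f"tads_{ct}.bed")
            pio.write_bedgraph(self.compartment_values[ct], out / f"compartments_{ct}.bedgraph")
            pio.write_bed(self.peaks[ct][["chrom", "start", "end"]], out / f"peaks_{ct}.bed")
        pio.write_bed(self.gaps, out / "gaps.bed")
        variants = self.haplotype_panel.variants.copy()
        variants["pos"] = variants["pos"] + 1
        hap_cols = pd.DataFrame(
            self.haplotype_panel.matrix,
            columns=[f"h{i}" for i in range(self.haplotype_panel.n_haplotypes)],
        )
        pio.write_table(pd.concat([variants, hap_cols], axis=1), out / "haplotypes.tsv")
        tags = self.tag_snps.copy()
        tags["pos"] = tags["pos"] + 1
        pio.write_table(tags, out / "tag_snps.tsv")
        eq = self.eqtls.copy()
        eq["pos"] = eq["pos"] + 1
        pio.write_table(eq.drop(columns=["planted"]), out / "eqtls.tsv")
        pio.write_table(self.expression.reset_index(names="gene"), out / "expression.tsv")
        pio.write_table(pd.DataFrame({"gene": self.phenotype_genes}), out / "phenotype_genes.tsv")
        (out / "go.obo").write_text(self.go_obo_text)
        go_rows = [(g, t) for g in sorted(self.gene_go) for t in sorted(self.gene_go[g])]
        with open(out / "gene_go.tsv", "w") as fh:
            for g, t in go_rows:
                fh.write(f"{g}\t{t}\n")
        pio.write_table(self.truth_loops, out / "truth" / "loops.tsv")
        pio.write_table(eq, out / "truth" / "eqtls.tsv")
        for ct in CELL_TYPES:
            pio.write_table(self.peaks[ct], out / "truth" / f"peaks_{ct}.tsv")


# ---------------------------------------------------------------------------
# generation steps


def _simulate_cuts(rng: np.random.Generator, layout: GenomeLayout, mean_bp: int) -> dict[str, np.ndarray]:
    cuts = {}
    for chrom, length in layout.lengths.items():
        n_target = int(length / mean_bp * 1.2) + 10
        gaps = rng.exponential(mean_bp, size=n_target)
        pos = np.cumsum(gaps).astype(np.int64)
        pos = pos[(pos > 0) & (pos < length)]
        cuts[chrom] = np.unique(pos)
    return cuts


def _simulate_tss(rng: np.random.Generator, layout: GenomeLayout, cfg: SimConfig) -> TssCatalog:
    total = sum(layout.lengths.values())
    rows = []
    gene_no = 0
    for chrom, length in layout.lengths.items():
        n = max(2, int(round(cfg.n_genes * length / total)))
        lo, hi = cfg.tss_edge_margin, length - cfg.tss_edge_margin
        # evenly spaced slots with jitter keeps the minimum spacing simple
        slots = np.linspace(lo, hi, n)
        jitter = rng.uniform(-0.3, 0.3, size=n) * (hi - lo) / max(n, 1)
        pos = np.sort((slots + jitter).astype(np.int64))
        pos = np.clip(pos, lo, hi)
        # enforce spacing
        for i in range(1, n):
            if pos[i] - pos[i - 1] < cfg.tss_min_spacing:
                pos[i] = pos[i - 1] + cfg.tss_min_spacing
        pos = pos[pos < hi]
        for p in pos:
            gene_no += 1
            rows.append((f"G{gene_no:05d}", chrom, int(p), "+" if rng.random() < 0.5 else "-"))
    return TssCatalog(pd.DataFrame(rows, columns=["gene", "chrom", "pos", "strand"]))


def _sample_span(rng: np.random.Generator, cfg: SimConfig) -> float:
    """Truncated power-law span d ~ d^-alpha on [min_span + margin, max_span]."""
    a = cfg.decay_alpha
    lo = float(cfg.min_span_bp + cfg.span_margin_bp)
    hi = float(cfg.max_span_bp)
    u = rng.random()
    if abs(a - 1.0) < 1e-9:
        return lo * (hi / lo) ** u
    b = 1.0 - a
    return (lo**b + u * (hi**b - lo**b)) ** (1.0 / b)


def _simulate_true_loops(
    rng: np.random.Generator,
    cfg: SimConfig,
    layout: GenomeLayout,
    fragment_map: FragmentMap,
    tss_catalog: TssCatalog,
    baits: BaitSet,
    promoter_regions: list[PromoterRegion],
) -> pd.DataFrame:
    """Sample distance-decaying promoter-distal loops and split by cell type."""
    bait_fragments = baits.fragments()
    region_by_gene = {g: r for r in promoter_regions for g in r.genes}
    rows = []
    for gene in baits.genes():
        chrom, _, _ = tss_catalog.tss_of(gene)
        region = region_by_gene[gene]
        anchor_ref = (region.start + region.end) // 2  # spans measured from promoter midpoint
        length = layout[chrom]
        n_loops = rng.poisson(cfg.loops_per_promoter)
        taken: list[int] = []
        for _ in range(n_loops):
            for _attempt in range(200):
                d = _sample_span(rng, cfg)
                sign = 1 if rng.random() < 0.5 else -1
                pos = int(anchor_ref + sign * d)
                if not 0 <= pos < length:
                    continue
                frag = fragment_map.fragment_at(chrom, pos)
                if frag in bait_fragments:
                    continue
                _, fs, fe = fragment_map.interval(frag)
                if fe > region.start - 1 and fs < region.end + 1:
                    continue
                if any(abs(fs - t) < cfg.anchor_min_separation for t in taken):
                    continue
                taken.append(fs)
                u = rng.random()
                if u < cfg.shared_fraction:
                    cells = "both"
                else:
                    cells = "CM" if rng.random() < 0.5 else "iPSC"
                rows.append((gene, chrom, int(frag), fs, fe, cells))
                break
    frame = pd.DataFrame(rows, columns=["gene", "chrom", "fragment", "start", "end", "cells"])
    return frame.sort_values(["chrom", "start", "gene"]).reset_index(drop=True)


def _observe_replicates(
    rng: np.random.Generator,
    cfg: SimConfig,
    fragment_map: FragmentMap,
    region_by_gene: dict[str, PromoterRegion],
    true_loops: pd.DataFrame,
    cell_type: str,
    bait_fragments: set[int],
) -> dict[str, list[Interaction]]:
    loops = true_loops[(true_loops["cells"] == "both") | (true_loops["cells"] == cell_type)]
    n_noise = int(round(cfg.noise_rate * len(loops)))
    genes = list(region_by_gene)
    out: dict[str, list[Interaction]] = {}
    for r in range(1, cfg.n_replicates + 1):
        label = f"rep{r}"
        records: list[Interaction] = []
        for loop in loops.itertuples():
            if rng.random() < cfg.dropout:
                continue
            frag = int(loop.fragment)
            if rng.random() < cfg.jitter_prob:  # report an adjacent fragment instead
                lo, hi = fragment_map.index_range(loop.chrom)
                neighbours = [f for f in (frag - 1, frag + 1) if lo <= f < hi]
                if neighbours:
                    frag = neighbours[int(rng.integers(len(neighbours)))]
            chrom, fs, fe = fragment_map.interval(frag)
            region = region_by_gene[loop.gene]
            records.append(
                Interaction(
                    gene=loop.gene,
                    chrom=region.chrom,
                    bait_start=region.start,
                    bait_end=region.end,
                    other_chrom=chrom,
                    other_start=fs,
                    other_end=fe,
                    score=float(rng.uniform(5.0, 15.0)),
                    replicate=label,
                )
            )
        for _ in range(n_noise):
            gene = genes[rng.integers(len(genes))]
            region = region_by_gene[gene]
            length = fragment_map.layout[region.chrom]
            for _attempt in range(100):
                pos = int(rng.integers(0, length))
                frag = fragment_map.fragment_at(region.chrom, pos)
                if frag in bait_fragments:
                    continue
                chrom, fs, fe = fragment_map.interval(frag)
                mid = (fs + fe) / 2
                if abs(mid - (region.start + region.end) / 2) < cfg.min_span_bp:
                    continue
                records.append(
                    Interaction(
                        gene=gene,
                        chrom=region.chrom,
                        bait_start=region.start,
                        bait_end=region.end,
                        other_chrom=chrom,
                        other_start=fs,
                        other_end=fe,
                        score=float(rng.uniform(5.0, 15.0)),
                        replicate=label,
                    )
                )
                break
        out[label] = records
    return out


def _simulate_tads(rng: np.random.Generator, cfg: SimConfig, layout: GenomeLayout) -> DomainSet:
    mu = np.log(cfg.tad_median_bp)
    rows = []
    for chrom, length in layout.lengths.items():
        pos = 0
        while pos < length:
            size = int(rng.lognormal(mu, cfg.tad_sigma))
            size = max(100_000, min(size, length - pos))
            rows.append((chrom, pos, pos + size, "domain"))
            pos += size
            if pos >= length:
                break
            if rng.random() < cfg.gap_prob:
                sep = min(cfg.gap_bp, length - pos)
                rows.append((chrom, pos, pos + sep, "gap"))
            else:
                sep = min(cfg.boundary_bp, length - pos)
                rows.append((chrom, pos, pos + sep, "boundary"))
            pos += sep
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    frame = frame[frame["end"] > frame["start"]]
    return DomainSet(frame)


def _simulate_compartments(
    rng: np.random.Generator, cfg: SimConfig, layout: GenomeLayout
) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows_a, rows_b = [], []
    for chrom, length in layout.lengths.items():
        pos = 0
        label = "A" if rng.random() < 0.5 else "B"
        while pos < length:
            size = int(rng.lognormal(np.log(cfg.compartment_mean_bp), 0.4))
            size = max(150_000, min(size, length - pos))
            value = rng.uniform(0.3, 1.5)
            rows_a.append((chrom, pos, pos + size, value if label == "A" else -value))
            flip = rng.random() < cfg.compartment_switch_prob
            label2 = ("B" if label == "A" else "A") if flip else label
            value2 = rng.uniform(0.3, 1.5)
            rows_b.append((chrom, pos, pos + size, value2 if label2 == "A" else -value2))
            pos += size
            label = "B" if label == "A" else "A"  # alternate, compartments interleave
    cols = ["chrom", "start", "end", "value"]
    return pd.DataFrame(rows_a, columns=cols), pd.DataFrame(rows_b, columns=cols)


def _simulate_peaks(
    rng: np.random.Generator,
    cfg: SimConfig,
    fragment_map: FragmentMap,
    true_loops: pd.DataFrame,
    cell_type: str,
    bait_fragments: set[int],
    compartment_values: pd.DataFrame,
) -> pd.DataFrame:
    """Peaks at this cell type's loop anchors (pi_peak) and elsewhere (beta).

    Anchor fragments draw only from the planted-anchor rule, never from the
    background rate, so the planted fold is pi_peak/beta up to pool mixing.
    Background peaks are denser in A-compartment chromatin (factors that
    average to one), coupling local peak density to expression downstream.
    """
    loops = true_loops[(true_loops["cells"] == "both") | (true_loops["cells"] == cell_type)]
    anchor_frags = np.array(sorted(set(int(f) for f in loops["fragment"])), dtype=np.int64)
    track = CompartmentTrack.from_bedgraph(compartment_values)
    n = len(fragment_map)
    is_anchor = np.zeros(n, dtype=bool)
    is_anchor[anchor_frags] = True
    is_bait = np.zeros(n, dtype=bool)
    if bait_fragments:
        is_bait[np.fromiter(bait_fragments, dtype=np.int64)] = True
    bg_rate = np.full(n, cfg.peak_background_rate)
    for chrom in fragment_map.chromosomes:
        lo, hi = fragment_map.index_range(chrom)
        starts = fragment_map.starts(chrom)
        arrays = track.arrays(chrom)
        if arrays is None:
            continue
        c_starts, c_ends, c_labels = arrays
        i = np.searchsorted(c_starts, starts, side="right") - 1
        labels = np.full(starts.size, "", dtype=object)
        ok = i >= 0
        in_interval = ok & (starts < c_ends[np.clip(i, 0, None)])
        labels[in_interval] = c_labels[i[in_interval]]
        factor = np.where(labels == "A", cfg.peak_compartment_factor_a, np.where(labels == "B", cfg.peak_compartment_factor_b, 1.0))
        bg_rate[lo:hi] = cfg.peak_background_rate * factor.astype(float)
    u = rng.random(n)
    has_peak = np.where(is_anchor, u < cfg.peak_anchor_prob, u < bg_rate) & ~is_bait
    rows = []
    for chrom in fragment_map.chromosomes:
        lo, hi = fragment_map.index_range(chrom)
        local = np.nonzero(has_peak[lo:hi])[0]
        starts = fragment_map.starts(chrom)[local]
        ends = fragment_map.ends(chrom)[local]
        origin = np.where(is_anchor[lo:hi][local], "anchor", "background")
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "origin": origin}))
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=["chrom", "start", "end", "origin"])


def _simulate_haplotypes_and_tags(
    rng: np.random.Generator,
    cfg: SimConfig,
    layout: GenomeLayout,
    fragment_map: FragmentMap,
    true_loops: pd.DataFrame,
    promoter_regions: list[PromoterRegion],
) -> tuple[HaplotypePanel, pd.DataFrame]:
    """LD blocks around tag SNPs; tags optionally planted inside CM loop anchors."""
    cm_loops = true_loops[(true_loops["cells"] == "both") | (true_loops["cells"] == "CM")]
    disease_classes = ("arrhythmia", "myocardial_infarction", "heart_failure")
    region_bounds: dict[str, list[tuple[int, int]]] = {}
    for r in promoter_regions:
        region_bounds.setdefault(r.chrom, []).append((r.start, r.end))

    tag_rows = []
    var_rows = []
    matrices = []
    snp_no = 0
    half_block = cfg.ld_block_bp // 2
    for t in range(cfg.n_tag_snps):
        if len(cm_loops) and rng.random() < cfg.tag_in_anchor_frac:
            loop = cm_loops.iloc[int(rng.integers(len(cm_loops)))]
            chrom = loop["chrom"]
            tag_pos = int(rng.integers(loop["start"], loop["end"]))
            planted_gene = loop["gene"]
        else:
            chrom = list(layout.lengths)[int(rng.integers(len(layout.lengths)))]
            tag_pos = int(rng.integers(half_block, layout[chrom] - half_block))
            planted_gene = ""
        positions = np.arange(
            max(1, tag_pos - half_block), min(layout[chrom] - 1, tag_pos + half_block), cfg.ld_variant_spacing
        )
        positions = np.unique(np.append(positions, tag_pos))
        m = positions.size
        founders = rng.integers(0, 2, size=(2, m)).astype(np.int8)
        founders[1] = 1 - founders[0]  # maximally distinct founders
        which = rng.integers(0, 2, size=cfg.n_haplotypes)
        block = founders[which]
        mut = rng.random(size=block.shape) < cfg.ld_mutation_rate
        block = np.where(mut, 1 - block, block)
        tag_idx = int(np.where(positions == tag_pos)[0][0])
        # keep the tag polymorphic
        if block[:, tag_idx].min() == block[:, tag_idx].max():
            block[0, tag_idx] = 1 - block[0, tag_idx]
        names = []
        for p in positions:
            snp_no += 1
            names.append(f"rs{snp_no:06d}")
            var_rows.append((names[-1], chrom, int(p)))
        matrices.append(block.T)  # variants x haplotypes
        tag_rows.append(
            (
                names[tag_idx],
                chrom,
                tag_pos,
                disease_classes[t % len(disease_classes)],
                f"study{t + 1}",
                planted_gene,
            )
        )
    variants = pd.DataFrame(var_rows, columns=["snp", "chrom", "pos"])
    matrix = np.vstack(matrices) if matrices else np.empty((0, cfg.n_haplotypes), dtype=np.int8)
    panel = HaplotypePanel(variants, matrix)
    tags = pd.DataFrame(
        tag_rows, columns=["snp", "chrom", "pos", "disease_class", "study", "planted_gene"]
    )
    return panel, tags


def _simulate_eqtls(
    rng: np.random.Generator,
    cfg: SimConfig,
    layout: GenomeLayout,
    tss_catalog: TssCatalog,
    true_loops: pd.DataFrame,
    promoter_regions: list[PromoterRegion],
) -> pd.DataFrame:
    """eQTLs with a planted probability of looping to their own gene (CM loops)."""
    cm_loops = true_loops[(true_loops["cells"] == "both") | (true_loops["cells"] == "CM")]
    loops_by_gene = {g: grp for g, grp in cm_loops.groupby("gene")}
    genes_with_loops = sorted(loops_by_gene)
    region_bounds: dict[str, list[tuple[int, int]]] = {}
    for r in promoter_regions:
        region_bounds.setdefault(r.chrom, []).append((r.start, r.end))
    rows = []
    if not genes_with_loops:
        return pd.DataFrame(columns=["variant", "chrom", "pos", "gene", "significant", "planted"])
    for i in range(cfg.n_eqtls):
        gene = genes_with_loops[int(rng.integers(len(genes_with_loops)))]
        chrom, tss, _ = tss_catalog.tss_of(gene)
        if rng.random() < cfg.eqtl_loop_preference:
            grp = loops_by_gene[gene]
            loop = grp.iloc[int(rng.integers(len(grp)))]
            pos = int(rng.integers(loop["start"], loop["end"]))
            planted = True
        else:
            planted = False
            for _attempt in range(500):
                pos = int(rng.integers(0, layout[chrom]))
                if abs(pos - tss) < cfg.min_span_bp:
                    continue
                if any(s <= pos < e for s, e in region_bounds.get(chrom, ())):
                    continue
                break
        rows.append((f"eqtl{i + 1:05d}", chrom, pos, gene, True, planted))
    return pd.DataFrame(rows, columns=["variant", "chrom", "pos", "gene", "significant", "planted"])


def _simulate_expression(
    rng: np.random.Generator,
    cfg: SimConfig,
    tss_catalog: TssCatalog,
    compartments: dict[str, pd.DataFrame],
    peaks: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """TPM per gene and replicate, coupled to compartment and peak density."""
    from .enrichment import FeatureIndex

    genes = list(tss_catalog.genes)
    base = rng.normal(cfg.expr_base_log2, cfg.expr_sd_log2, size=len(genes))
    zero = rng.random(len(genes)) < cfg.expr_zero_prob
    data = {}
    for ct in CELL_TYPES:
        track = CompartmentTrack.from_bedgraph(compartments[ct])
        peak_index = FeatureIndex(peaks[ct])
        mu = np.empty(len(genes))
        for gi, gene in enumerate(genes):
            chrom, pos, _ = tss_catalog.tss_of(gene)
            in_a = track.label_at(chrom, pos) == "A"
            density = peak_index.count_in(chrom, pos - 300_000, pos + 300_000)
            mu[gi] = base[gi] + (cfg.compartment_effect_log2 if in_a else 0.0) + cfg.peak_density_effect_log2 * np.log1p(density)
        for r in range(1, 4):
            noise = rng.normal(0.0, cfg.expr_replicate_sd, size=len(genes))
            tpm = np.where(zero, 0.0, 2.0 ** (mu + noise))
            data[f"{ct}_rep{r}"] = np.round(tpm, 3)
    return pd.DataFrame(data, index=pd.Index(genes, name="gene"))


def _simulate_annotations(
    rng: np.random.Generator,
    tss_catalog: TssCatalog,
    tags: pd.DataFrame,
) -> tuple[list[str], str, dict[str, set[str]]]:
    """Phenotype gene list and a toy ontology with a planted enriched term.

    Genes targeted by a planted tag SNP carry the phenotype (and the
    'cardiac'-like leaf term) with elevated probability, so annotation-based
    enrichment stages have real signal to find.
    """
    planted_targets = set(tags["planted_gene"]) - {""}
    genes = list(tss_catalog.genes)
    phenotype = [
        g for g in genes if rng.random() < (0.5 if g in planted_targets else 0.1)
    ]
    terms = {
        "T:0000001": ("biological process", None),
        "T:0000002": ("cell signaling", "T:0000001"),
        "T:0000003": ("muscle development", "T:0000001"),
        "T:0000004": ("cardiac muscle contraction", "T:0000003"),
        "T:0000005": ("metabolism", "T:0000001"),
    }
    lines = ["format-version: 1.2", "ontology: toy", ""]
    for tid, (name, parent) in terms.items():
        lines += ["[Term]", f"id: {tid}", f"name: {name}"]
        if parent:
            lines.append(f"is_a: {parent} ! {terms[parent][0]}")
        lines.append("")
    assoc: dict[str, set[str]] = {}
    leaf_terms = ["T:0000002", "T:0000004", "T:0000005"]
    for g in genes:
        got: set[str] = set()
        if g in planted_targets or rng.random() < 0.08:
            got.add("T:0000004")
        for t in ("T:0000002", "T:0000005"):
            if rng.random() < 0.2:
                got.add(t)
        if not got:
            got.add(leaf_terms[int(rng.integers(len(leaf_terms)))])
        assoc[g] = got
    return phenotype, "\n".join(lines), assoc


def simulate_dataset(config: SimConfig | None = None, **overrides) -> SimBundle:
    """Generate a complete synthetic dataset bundle from a config.

    Keyword overrides are applied on top of ``config`` (or the defaults), so
    ``simulate_dataset(seed=7, n_genes=40)`` is a convenient short form.
    """
    cfg = config or SimConfig()
    if overrides:
        cfg = dataclasses.replace(cfg, **overrides)
    layout = GenomeLayout(dict(cfg.chrom_lengths))
    cfg.validate(layout)
    rng = np.random.default_rng(cfg.seed)

    fragment_map = build_fragment_map(layout, _simulate_cuts(rng, layout, cfg.mean_fragment_bp))
    tss_catalog = _simulate_tss(rng, layout, cfg)
    baits = select_bait_fragments(tss_catalog, fragment_map)
    promoter_regions = merge_promoter_regions(baits, tss_catalog, fragment_map)
    region_by_gene = {g: r for r in promoter_regions for g in r.genes}
    bait_fragments = baits.fragments()

    true_loops = _simulate_true_loops(rng, cfg, layout, fragment_map, tss_catalog, baits, promoter_regions)
    interactions = {
        ct: _observe_replicates(rng, cfg, fragment_map, region_by_gene, true_loops, ct, bait_fragments)
        for ct in CELL_TYPES
    }
    domains = {ct: _simulate_tads(rng, cfg, layout) for ct in CELL_TYPES}
    comp_a, comp_b = _simulate_compartments(rng, cfg, layout)
    compartment_values = {"iPSC": comp_a, "CM": comp_b}
    peaks = {
        ct: _simulate_peaks(rng, cfg, fragment_map, true_loops, ct, bait_fragments, compartment_values[ct])
        for ct in CELL_TYPES
    }
    panel, tags = _simulate_haplotypes_and_tags(rng, cfg, layout, fragment_map, true_loops, promoter_regions)
    eqtls = _simulate_eqtls(rng, cfg, layout, tss_catalog, true_loops, promoter_regions)
    expression = _simulate_expression(rng, cfg, tss_catalog, compartment_values, peaks)
    phenotype_genes, obo_text, gene_go = _simulate_annotations(rng, tss_catalog, tags)

    gaps = pd.concat(
        [d.frame[d.frame["label"] == "gap"][["chrom", "start", "end"]] for d in domains.values()]
    )
    gaps = gaps.drop_duplicates().sort_values(["chrom", "start"]).reset_index(drop=True)

    return SimBundle(
        config=cfg,
        layout=layout,
        fragment_map=fragment_map,
        tss_catalog=tss_catalog,
        baits=baits,
        promoter_regions=promoter_regions,
        interactions=interactions,
        domains=domains,
        compartment_values=compartment_values,
        peaks=peaks,
        gaps=gaps,
        haplotype_panel=panel,
        tag_snps=tags,
        eqtls=eqtls,
        expression=expression,
        truth_loops=true_loops,
        phenotype_genes=phenotype_genes,
        go_obo_text=obo_text,
        gene_go=gene_go,
        truth={"config": dataclasses.asdict(cfg)},
    )


def consensus_for(bundle: SimBundle, cell_type: str, *, min_support: int = 2) -> list[ConsensusInteraction]:
    """Convenience: distance filter + replicate consensus for one cell type."""
    per_rep = {
        rep: filter_min_distance(records, bundle.config.min_span_bp)
        for rep, records in bundle.interactions[cell_type].items()
    }
    return replicate_consensus(per_rep, min_support=min_support)


def truth_report(
    bundle: SimBundle,
    consensus_by_cell_type: dict[str, list[ConsensusInteraction]],
    *,
    ext: int = 1_000,
) -> dict:
    """Score pipeline outputs against the planted truth.

    A true loop counts as recovered when a consensus interaction of the same
    gene overlaps its anchor fragment within the 1 kb extension; a consensus
    interaction is a true positive when it overlaps a true anchor of its
    gene under the same rule.
    """
    report: dict = {}
    for ct, consensus in consensus_by_cell_type.items():
        loops = bundle.truth_loops[
            (bundle.truth_loops["cells"] == "both") | (bundle.truth_loops["cells"] == ct)
        ]
        cons_by_gene: dict[str, list[ConsensusInteraction]] = {}
        for c in consensus:
            cons_by_gene.setdefault(c.gene, []).append(c)
        recovered = 0
        for loop in loops.itertuples():
            hit = any(
                c.distal_start - ext < loop.end and loop.start < c.distal_end + ext
                for c in cons_by_gene.get(loop.gene, ())
            )
            recovered += hit
        loops_by_gene = {g: grp for g, grp in loops.groupby("gene")}
        true_pos = 0
        for c in consensus:
            grp = loops_by_gene.get(c.gene)
            if grp is not None and (
                (grp["start"].values < c.distal_end + ext) & (c.distal_start - ext < grp["end"].values)
            ).any():
                true_pos += 1
        report[ct] = {
            "n_true_loops": int(len(loops)),
            "n_consensus": len(consensus),
            "loop_recall": recovered / len(loops) if len(loops) else float("nan"),
            "loop_precision": true_pos / len(consensus) if consensus else float("nan"),
        }
    return report
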