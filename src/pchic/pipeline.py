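"""End-to-end orchestration over a directory of pipeline inputs.

A run consumes an input directory laid out as the synthetic generator emits
it (or equivalently prepared real data), executes the requested stages in
dependency order, writes tab-separated outputs under the output directory
and finishes with an atomic ``manifest.json`` carrying the config snapshot,
input checksums, seeds, package version and per-stage timings. Reruns with
identical inputs and seed are idempotent (byte-identical analysis outputs;
the manifest's wall-clock timings are the only varying field).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as pio
from .compartments import (
    CompartmentTrack,
    ab_expression_test,
    assign_compartment,
    classify_switch,
    log2fc_from_tpm,
    switch_expression_test,
)
from .consensus import (
    build_captured_index,
    categorize_interaction,
    distance_summary,
    filter_min_distance,
    replicate_consensus,
    split_specific_shared,
)
from .enrichment import (
    BackgroundSampler,
    binned_enrichment,
    distal_fragments,
    enrichment,
    peak_density_expression_corr,
    promoter_distal_peaks,
    specificity_matrix,
)
from .genome import BaitSet, GenomeLayout, merge_promoter_regions
from .gwas import HaplotypePanel, ld_expand, link_snps, link_summary
from .locus_stats import (
    eqtl_loop_enrichment,
    filter_promoter_distal_eqtls,
    geneset_resample_enrichment,
    go_enrichment,
)
from .records import ConsensusInteraction
from .tads import DomainSet, boundary_distance, classify_tad

logger = logging.getLogger(__name__)

__all__ = ["PipelineRun", "STAGES", "run_stages"]

CELL_TYPES = ("iPSC", "CM")

STAGES = (
    "consensus",
    "categorize",
    "tad",
    "enrich",
    "corr",
    "link",
    "eqtl",
    "geneset",
    "go",
    "compartments",
    "report",
)

_DEPENDENCIES = {
    "categorize": ("consensus",),
    "tad": ("consensus",),
    "enrich": ("consensus",),
    "corr": ("consensus",),
    "link": ("consensus",),
    "eqtl": ("consensus",),
    "geneset": ("link",),
    "go": ("link",),
    "compartments": (),
    "report": ("consensus",),
}

_STAGE_OUTPUTS = {
    "consensus": ("consensus_CM.tsv", "consensus_iPSC.tsv"),
    "categorize": ("categories_CM.tsv",),
    "tad": ("tad_classes_CM.tsv",),
    "enrich": ("enrichment_CM.tsv",),
    "corr": ("expression_peak_corr.tsv",),
    "link": ("snp_gene_links.tsv",),
    "eqtl": ("eqtl_enrichment.tsv",),
    "geneset": ("geneset_enrichment.tsv",),
    "go": ("go_enrichment.tsv",),
    "compartments": ("compartment_switches.tsv",),
    "report": ("report.json",),
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineRun:
    """Loads pipeline inputs once and runs stages against them."""

    def __init__(self, input_dir, output_dir, *, seed: int = 1, config: dict | None = None):
        self.input_dir = Path(input_dir)
        self.output_dir = Path(output_dir)
        self.seed = int(seed)
        self.config = dict(config or {})
        self.output_dir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "version": __version__,
            "seed": self.seed,
            "config": self.config,
            "input_dir": str(self.input_dir),
            "inputs": {},
            "stages": {},
            "outputs": [],
        }
        self._load_inputs()
        self._consensus: dict[str, list[ConsensusInteraction]] | None = None
        self._specific: dict[str, tuple[list, list]] | None = None

    # -- input loading -----------------------------------------------------

    def _load_inputs(self) -> None:
        d = self.input_dir
        frag_bed = pio.read_bed(d / "fragments.bed")
        lengths = {c: int(g["end"].max()) for c, g in frag_bed.groupby("chrom", sort=False)}
        self.layout = GenomeLayout(lengths)
        self.fragment_map = pio.read_fragment_map_bed(d / "fragments.bed", self.layout)
        self.tss_catalog = pio.read_tss_table(d / "tss.tsv")
        bait_table = pio.read_table(d / "baits.tsv")
        baits: dict[str, list[int]] = {}
        for row in bait_table.itertuples():
            baits.setdefault(row.gene, []).append(int(row.fragment_id))
        self.baits = BaitSet({g: tuple(sorted(v)) for g, v in baits.items()})
        self.promoter_regions = merge_promoter_regions(self.baits, self.tss_catalog, self.fragment_map)
        self.interactions = {ct: {} for ct in CELL_TYPES}
        for path in sorted((d / "interactions").glob("*.ibed")):
            ct, _, rep = path.stem.partition("_")
            self.interactions[ct][rep] = pio.read_interactions(path, "ibed", replicate=rep)
        self.domains = {
            ct: DomainSet(pio.read_bed(d / f"tads_{ct}.bed").rename(columns={"name": "label"}))
            for ct in CELL_TYPES
        }
        self.compartments = {
            ct: CompartmentTrack.from_bedgraph(pio.read_bedgraph(d / f"compartments_{ct}.bedgraph"))
            for ct in CELL_TYPES
        }
        self.peaks = {ct: pio.read_bed(d / f"peaks_{ct}.bed") for ct in CELL_TYPES}
        self.gaps = pio.read_bed(d / "gaps.bed") if (d / "gaps.bed").exists() else pd.DataFrame(columns=["chrom", "start", "end"])
        hap = pio.read_table(d / "haplotypes.tsv")
        hap_cols = [c for c in hap.columns if c.startswith("h")]
        variants = hap[["snp", "chrom", "pos"]].copy()
        variants["pos"] = variants["pos"].astype(int) - 1
        self.haplotype_panel = HaplotypePanel(variants, hap[hap_cols].to_numpy())
        tags = pio.read_table(d / "tag_snps.tsv")
        tags["pos"] = tags["pos"].astype(int) - 1
        self.tag_snps = tags
        eq = pio.read_table(d / "eqtls.tsv")
        eq["pos"] = eq["pos"].astype(int) - 1
        self.eqtls = eq
        self.expression = pio.read_table(d / "expression.tsv").set_index("gene")
        self.phenotype_genes = (
            set(pio.read_table(d / "phenotype_genes.tsv")["gene"]) if (d / "phenotype_genes.tsv").exists() else set()
        )
        self.go_dag = pio.read_obo_lite(d / "go.obo") if (d / "go.obo").exists() else None
        self.gene_go = (
            pio.read_gene_associations(d / "gene_go.tsv", self.go_dag) if (d / "gene_go.tsv").exists() else {}
        )
        for path in sorted(d.rglob("*")):
            if path.is_file():
                self.manifest["inputs"][str(path.relative_to(d))] = _sha256(path)

    # -- helpers -----------------------------------------------------------

    def mean_tpm(self, cell_type: str) -> dict[str, float]:
        cols = [c for c in self.expression.columns if c.startswith(cell_type + "_")]
        return self.expression[cols].mean(axis=1).to_dict()

    def exclude_regions(self) -> list[tuple[str, int, int]]:
        out = [(r.chrom, r.start, r.end) for r in self.promoter_regions]
        out += [(r.chrom, int(r.start), int(r.end)) for r in self.gaps.itertuples()]
        return out

    def _require(self, stage: str) -> None:
        for dep in _DEPENDENCIES.get(stage, ()):
            missing = [f for f in _STAGE_OUTPUTS[dep] if not (self.output_dir / f).exists()]
            if missing:
                raise RuntimeError(
                    f"stage {stage!r} requires outputs of stage {dep!r}; run {dep!r} first "
                    f"(missing: {missing})"
                )

    def _get_consensus(self) -> dict[str, list[ConsensusInteraction]]:
        if self._consensus is None:
            self._consensus = {}
            self._specific = {}
            for ct in CELL_TYPES:
                per_rep = {r: filter_min_distance(recs) for r, recs in self.interactions[ct].items()}
                cons = replicate_consensus(per_rep)
                other = CELL_TYPES[1] if ct == CELL_TYPES[0] else CELL_TYPES[0]
                spec, shared = split_specific_shared(cons, self.interactions[other])
                self._consensus[ct] = cons
                self._specific[ct] = (spec, shared)
        return self._consensus

    def _write_consensus_tsv(self, ct: str) -> None:
        cons = self._get_consensus()[ct]
        spec_set = set(self._specific[ct][0])
        rows = [
            (
                c.gene,
                c.chrom,
                c.promoter_start,
                c.promoter_end,
                c.distal_start,
                c.distal_end,
                ",".join(c.replicates),
                max(c.scores),
                int(c.span_distance),
                "specific" if c in spec_set else "shared",
            )
            for c in cons
        ]
        frame = pd.DataFrame(
            rows,
            columns=[
                "gene",
                "chrom",
                "promoter_start",
                "promoter_end",
                "distal_start",
                "distal_end",
                "replicates",
                "max_score",
                "span_bp",
                "specificity",
            ],
        )
        pio.write_table(frame, self.output_dir / f"consensus_{ct}.tsv")
        pio.write_washu_track(cons, self.output_dir / f"consensus_{ct}.longrange.txt")

    # -- stages ------------------------------------------------------------

    def stage_consensus(self) -> None:
        self._get_consensus()
        for ct in CELL_TYPES:
            self._write_consensus_tsv(ct)

    def stage_categorize(self) -> None:
        captured = build_captured_index(self.baits, self.tss_catalog, self.fragment_map)
        for ct in CELL_TYPES:
            cons = self._get_consensus()[ct]
            frame = pd.DataFrame(
                {
                    "gene": [c.gene for c in cons],
                    "chrom": [c.chrom for c in cons],
                    "distal_start": [c.distal_start for c in cons],
                    "distal_end": [c.distal_end for c in cons],
                    "category": [categorize_interaction(c, captured) for c in cons],
                }
            )
            pio.write_table(frame, self.output_dir / f"categories_{ct}.tsv")

    def stage_tad(self) -> None:
        region_by_gene = {g: r for r in self.promoter_regions for g in r.genes}
        for ct in CELL_TYPES:
            cons = self._get_consensus()[ct]
            classes = [classify_tad(c, self.domains[ct]) for c in cons]
            bdist = []
            for c in cons:
                region = region_by_gene.get(c.gene)
                try:
                    bdist.append(boundary_distance(region, self.domains[ct]) if region else np.nan)
                except ValueError:
                    bdist.append(np.nan)
            frame = pd.DataFrame(
                {
                    "gene": [c.gene for c in cons],
                    "chrom": [c.chrom for c in cons],
                    "span_bp": [int(c.span_distance) for c in cons],
                    "tad_class": classes,
                    "promoter_boundary_bp": bdist,
                }
            )
            pio.write_table(frame, self.output_dir / f"tad_classes_{ct}.tsv")

    def stage_enrich(self) -> None:
        iters = int(self.config.get("enrichment_iterations", 100))
        sampler = BackgroundSampler(self.fragment_map, self.exclude_regions(), seed=self.seed)
        rows = []
        cons = self._get_consensus()
        for ct in CELL_TYPES:
            peaks = promoter_distal_peaks(self.peaks[ct], self.promoter_regions)
            frags = distal_fragments(cons[ct], self.fragment_map)
            res = enrichment(frags, peaks, sampler, iterations=iters, seed=self.seed)
            rows.append((ct, "all", res.observed, res.null_mean, res.fold, res.z, res.p, res.iterations, res.seed))
            binned = binned_enrichment(self.mean_tpm(ct), cons[ct], peaks, sampler, iterations=iters, seed=self.seed)
            for b, r in binned.items():
                rows.append((ct, f"bin{b}", r.observed, r.null_mean, r.fold, r.z, r.p, r.iterations, r.seed))
        frame = pd.DataFrame(
            rows, columns=["cell_type", "group", "observed", "null_mean", "fold", "z", "p", "iterations", "seed"]
        )
        pio.write_table(frame, self.output_dir / "enrichment_CM.tsv")
        # 3x3 specificity grid, CM/iPSC specific and shared interactions vs peak classes
        spec_cm, shared_cm = self._specific["CM"]
        spec_ip, _ = self._specific["iPSC"]
        grid = specificity_matrix(
            {"A_specific": spec_ip, "B_specific": spec_cm, "shared": shared_cm},
            promoter_distal_peaks(self.peaks["iPSC"], self.promoter_regions),
            promoter_distal_peaks(self.peaks["CM"], self.promoter_regions),
            sampler,
            iterations=iters,
            seed=self.seed,
        )
        pio.write_table(grid, self.output_dir / "specificity_matrix.tsv")

    def stage_corr(self) -> None:
        rows = []
        cons = self._get_consensus()
        for ct in CELL_TYPES:
            genes = {c.gene for c in cons[ct]}
            peaks = promoter_distal_peaks(self.peaks[ct], self.promoter_regions)
            rho, p = peak_density_expression_corr(
                self.mean_tpm(ct), peaks, self.tss_catalog, genes_with_interaction=genes
            )
            rows.append((ct, rho, p))
        pio.write_table(
            pd.DataFrame(rows, columns=["cell_type", "spearman_rho", "p"]),
            self.output_dir / "expression_peak_corr.tsv",
        )

    def stage_link(self) -> None:
        cons = self._get_consensus()["CM"]
        ld = ld_expand(self.tag_snps, self.haplotype_panel)
        links = link_snps(
            ld, cons, self.promoter_regions, self.tss_catalog, domains=self.domains["CM"]
        )
        frame = pd.DataFrame(
            {
                "snp": [l.snp for l in links],
                "chrom": [l.chrom for l in links],
                "pos": [l.pos + 1 for l in links],
                "gene": [l.gene for l in links],
                "distance_bp": [int(l.distance) for l in links],
                "same_tad": [l.same_tad for l in links],
                "skipped_tss": [l.skipped_tss for l in links],
                "disease_class": [l.disease_class for l in links],
            }
        )
        pio.write_table(frame, self.output_dir / "snp_gene_links.tsv")
        summary = link_summary(links)
        summary["n_ld_snps"] = len(ld)
        with open(self.output_dir / "link_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)

    def stage_eqtl(self) -> None:
        n_perm = int(self.config.get("eqtl_permutations", 1000))
        cons = self._get_consensus()
        rows = []
        for ct in CELL_TYPES:
            eq = filter_promoter_distal_eqtls(self.eqtls, self.tss_catalog, self.promoter_regions)
            res = eqtl_loop_enrichment(
                eq, cons[ct], self.tss_catalog, self.layout, n_perm=n_perm, seed=self.seed
            )
            rows.append(
                (ct, res.observed, float(np.mean(res.permuted)), float(np.std(res.permuted)), res.z, res.p, res.p_empirical, res.n_perm, res.seed)
            )
        pio.write_table(
            pd.DataFrame(
                rows,
                columns=["cell_type", "observed", "null_mean", "null_sd", "z", "p", "p_empirical", "n_perm", "seed"],
            ),
            self.output_dir / "eqtl_enrichment.tsv",
        )

    def _target_genes(self) -> list[str]:
        links = pio.read_table(self.output_dir / "snp_gene_links.tsv")
        return sorted(set(links["gene"])) if len(links) else []

    def stage_geneset(self) -> None:
        n_iter = int(self.config.get("geneset_iterations", 1000))
        targets = self._target_genes()
        pool = sorted({c.gene for c in self._get_consensus()["CM"]})
        if not targets:
            logger.warning("no target genes; gene-set stage writes an empty table")
            pio.write_table(pd.DataFrame(columns=["observed", "null_mean", "fold", "z", "p"]), self.output_dir / "geneset_enrichment.tsv")
            return
        res = geneset_resample_enrichment(
            targets, pool, self.phenotype_genes, n_iter=n_iter, seed=self.seed
        )
        frame = pd.DataFrame(
            [
                (
                    len(targets),
                    len(pool),
                    res.observed,
                    res.null_mean,
                    res.null_sd,
                    res.fold,
                    res.z,
                    res.p,
                    res.iterations,
                    res.seed,
                )
            ],
            columns=["n_targets", "n_pool", "observed", "null_mean", "null_sd", "fold", "z", "p", "iterations", "seed"],
        )
        pio.write_table(frame, self.output_dir / "geneset_enrichment.tsv")

    def stage_go(self) -> None:
        if self.go_dag is None or not self.gene_go:
            logger.warning("no ontology inputs; GO stage writes an empty table")
            pio.write_table(pd.DataFrame(columns=["term", "name", "p", "q"]), self.output_dir / "go_enrichment.tsv")
            return
        targets = self._target_genes()
        exclude = set(self.config.get("go_exclude_genes", ()))  # e.g. histone-cluster genes
        targets = [g for g in targets if g not in exclude]
        universe = [g for g in self.tss_catalog.genes if g not in exclude]
        results = go_enrichment(set(targets) & set(universe), universe, self.go_dag, self.gene_go)
        frame = pd.DataFrame(
            {
                "term": [r.term for r in results],
                "name": [r.name for r in results],
                "annotated_in_universe": [r.annotated_in_universe for r in results],
                "annotated_in_set": [r.annotated_in_set for r in results],
                "set_size": [r.set_size for r in results],
                "universe_size": [r.universe_size for r in results],
                "p": [r.p for r in results],
                "q": [r.q for r in results],
            }
        )
        pio.write_table(frame, self.output_dir / "go_enrichment.tsv")

    def stage_compartments(self) -> None:
        assign = {ct: assign_compartment(self.tss_catalog, self.compartments[ct]) for ct in CELL_TYPES}
        switches = classify_switch(assign["iPSC"], assign["CM"])
        log2fc = log2fc_from_tpm(self.mean_tpm("iPSC"), self.mean_tpm("CM"))
        frame = pd.DataFrame(
            {
                "gene": list(switches),
                "iPSC": [assign["iPSC"][g] for g in switches],
                "CM": [assign["CM"][g] for g in switches],
                "switch_class": list(switches.values()),
                "log2fc": [log2fc.get(g, np.nan) for g in switches],
            }
        ).sort_values("gene")
        pio.write_table(frame, self.output_dir / "compartment_switches.tsv")
        summary, pvals = switch_expression_test(switches, log2fc)
        pio.write_table(summary, self.output_dir / "compartment_summary.tsv")
        ab_rows = []
        for ct in CELL_TYPES:
            _, p = ab_expression_test(assign[ct], self.mean_tpm(ct))
            ab_rows.append((ct, p))
        extra = pd.DataFrame(
            [(f"{a}_vs_{b}", p) for (a, b), p in pvals.items()] + [(f"AB_expression_{ct}", p) for ct, p in ab_rows],
            columns=["comparison", "p"],
        )
        pio.write_table(extra, self.output_dir / "compartment_tests.tsv")

    def stage_report(self) -> None:
        cons = self._get_consensus()
        report: dict = {"seed": self.seed, "version": __version__}
        for ct in CELL_TYPES:
            summ = distance_summary(cons[ct]) if cons[ct] else {"median": None, "mean": None}
            spec, shared = self._specific[ct]
            report[ct] = {
                "n_consensus": len(cons[ct]),
                "n_specific": len(spec),
                "n_shared": len(shared),
                "median_span_bp": summ["median"],
                "mean_span_bp": summ["mean"],
            }
        with open(self.output_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)

    # -- driver ------------------------------------------------------------

    def run(self, stages=STAGES) -> dict:
        for stage in stages:
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r}; valid: {STAGES}")
            self._require(stage)
            t0 = time.perf_counter()
            getattr(self, f"stage_{stage}")()
            self.manifest["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 3)}
        self.manifest["outputs"] = sorted(
            str(p.relative_to(self.output_dir))
            for p in self.output_dir.glob("*")
            if p.is_file() and p.name != "manifest.json"
        )
        tmp = self.output_dir / "manifest.json.tmp"
        with open(tmp, "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
        os.replace(tmp, self.output_dir / "manifest.json")
        return self.manifest


def run_stages(input_dir, output_dir, stages=STAGES, *, seed: int = 1, config: dict | None = None) -> dict:
    """One-shot helper: load inputs, run ``stages``, return the manifest."""
    run = PipelineRun(input_dir, output_dir, seed=seed, config=config)
    return run.run(stages)
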