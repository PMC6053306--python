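"""Classify consensus interactions relative to TAD domains.

An interaction whose whole span lies inside one domain is intra-TAD; one
whose ends overlap two different domains is inter-TAD; ends in boundaries
or gaps stay unassigned.
"""

from pchic.simulate import SimConfig, consensus_for, simulate_dataset
from pchic.tads import boundary_distance, classify_tad

bundle = simulate_dataset(SimConfig(seed=1))
consensus = consensus_for(bundle, "CM")
domains = bundle.domains["CM"]

classes = [classify_tad(c, domains) for c in consensus]
for label in ("intra", "inter", "unassigned"):
    n = classes.count(label)
    print(f"{label}-TAD: {n} ({100 * n / len(classes):.1f}%)")
# intra-TAD dominates because loop spans are mostly shorter than domains

region_by_gene = {g: r for r in bundle.promoter_regions for g in r.genes}
inter_genes = {c.gene for c, k in zip(consensus, classes) if k == "inter"}
intra_genes = {c.gene for c, k in zip(consensus, classes) if k == "intra"} - inter_genes
for name, genes in [("inter-TAD", inter_genes), ("intra-only", intra_genes)]:
    dists = [boundary_distance(region_by_gene[g], domains) / 1e3 for g in genes]
    if dists:
        print(f"promoters with {name} interactions: "
              f"median distance to a domain edge {sorted(dists)[len(dists)//2]:.0f} kb")
# promoters looping across domains tend to sit closer to domain edges
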