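"""Classify interactions relative to topological domains (TADs).

Domain calls are consumed, never computed: the expected input is a BED file
with a label column distinguishing ``domain``, ``boundary`` and ``gap``
intervals (TopDom-style output is convertible with
:func:`domains_from_topdom`). Only ``domain`` intervals enter the
classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import ConsensusInteraction, Interaction

__all__ = ["DomainSet", "classify_tad", "boundary_distance", "domains_from_topdom"]


@dataclass
class DomainSet:
    """Per-chromosome sorted, non-overlapping intervals labeled domain/boundary/gap."""

    frame: pd.DataFrame  # columns: chrom, start, end, label

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "label"}
        if not required <= set(self.frame.columns):
            raise ValueError(f"DomainSet frame needs columns {sorted(required)}")
        self.frame = self.frame.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        domains = self.frame[self.frame["label"] == "domain"]
        for chrom, grp in domains.groupby("chrom", sort=False):
            s = grp["start"].to_numpy(dtype=np.int64)
            e = grp["end"].to_numpy(dtype=np.int64)
            if np.any(s[1:] < e[:-1]):
                raise ValueError(f"domains overlap on {chrom!r}")
            self._starts[chrom] = s
            self._ends[chrom] = e

    def domain_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        return (
            self._starts.get(chrom, np.empty(0, dtype=np.int64)),
            self._ends.get(chrom, np.empty(0, dtype=np.int64)),
        )

    def domains_overlapping(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Local indices of domains overlapping [start, end) by >= 1 bp."""
        s, e = self.domain_arrays(chrom)
        if s.size == 0 or end <= start:
            return np.empty(0, dtype=np.int64)
        lo = int(np.searchsorted(e, start, side="right"))
        hi = int(np.searchsorted(s, end, side="left"))
        return np.arange(lo, hi, dtype=np.int64)

    def domain_containing(self, chrom: str, pos: float) -> int | None:
        """Local index of the domain interval containing ``pos``, if any."""
        s, e = self.domain_arrays(chrom)
        if s.size == 0:
            return None
        i = int(np.searchsorted(s, pos, side="right")) - 1
        if i >= 0 and pos < e[i]:
            return i
        return None


def domains_from_topdom(frame: pd.DataFrame) -> DomainSet:
    """Adapt TopDom native output (chrom, start, end, tag) to a DomainSet.

    TopDom tags domains ``domain``, boundaries ``boundary`` and unmappable
    stretches ``gap``; any extra columns are dropped.
    """
    tags = frame.iloc[:, 3].astype(str).str.lower()
    out = pd.DataFrame(
        {
            "chrom": frame.iloc[:, 0],
            "start": frame.iloc[:, 1].astype(int),
            "end": frame.iloc[:, 2].astype(int),
            "label": tags.where(tags.isin(["domain", "boundary", "gap"]), "gap"),
        }
    )
    return DomainSet(out)


def classify_tad(interaction: ConsensusInteraction | Interaction, domains: DomainSet) -> str:
    """Classify an interaction as ``intra``, ``inter`` or ``unassigned``.

    ``intra``: the entire span (from the leftmost start of either end to the
    rightmost end) is fully contained in a single domain. ``inter``: each end
    overlaps exactly one domain and they differ. Everything else — an end in
    a boundary/gap, or straddling a domain edge — is ``unassigned``.
    """
    if isinstance(interaction, ConsensusInteraction):
        chrom = interaction.chrom
        a = (interaction.promoter_start, interaction.promoter_end)
        b = (interaction.distal_start, interaction.distal_end)
    else:
        if not interaction.is_cis:
            return "unassigned"
        chrom = interaction.chrom
        a = (interaction.bait_start, interaction.bait_end)
        b = (interaction.other_start, interaction.other_end)
    span = (min(a[0], b[0]), max(a[1], b[1]))
    s, e = domains.domain_arrays(chrom)
    if s.size:
        i = int(np.searchsorted(s, span[0], side="right")) - 1
        if i >= 0 and span[1] <= e[i]:
            return "intra"
    hits_a = domains.domains_overlapping(chrom, *a)
    hits_b = domains.domains_overlapping(chrom, *b)
    if hits_a.size == 1 and hits_b.size == 1 and hits_a[0] != hits_b[0]:
        return "inter"
    return "unassigned"


def boundary_distance(promoter, domains: DomainSet) -> float:
    """Distance (bp) from a promoter's midpoint to the nearest domain edge.

    ``promoter`` needs ``chrom`` and ``midpoint`` attributes (a
    :class:`~pchic.genome.PromoterRegion` fits). Raises when the chromosome
    has no domain calls.
    """
    s, e = domains.domain_arrays(promoter.chrom)
    if s.size == 0:
        raise ValueError(f"no domains on chromosome {promoter.chrom!r}")
    edges = np.concatenate([s, e]).astype(float)
    return float(np.min(np.abs(edges - promoter.midpoint)))
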