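"""Coordinate scaffold: chromosomes, restriction-fragment maps, TSS catalog,
bait selection and merged promoter regions.

All coordinates are 0-based, half-open internally. Readers convert 1-based
inclusive inputs at the I/O boundary (see :mod:`pchic.io`).

The fragment map is the universal scaffold of the toolkit: every interaction
end, ChIP-seq peak overlap and random background draw is expressed in terms
of restriction-fragment indices. Fragments tile each chromosome exactly, so
every base pair belongs to exactly one fragment and fragment indices are a
stable global coordinate system.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "FragmentMap",
    "TssCatalog",
    "BaitSet",
    "PromoterRegion",
    "build_fragment_map",
    "select_bait_fragments",
    "merge_promoter_regions",
]


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome name -> length in bp."""

    lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        if len(self.lengths) == 0:
            raise ValueError("genome layout must contain at least one chromosome")
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self.lengths)

    def __getitem__(self, name: str) -> int:
        return self.lengths[name]


class FragmentMap:
    """Ordered, non-overlapping restriction fragments tiling each chromosome.

    Fragments carry stable global indices, strictly increasing with
    coordinate; chromosomes are indexed in the order of the genome layout.
    """

    def __init__(self, layout: GenomeLayout, starts: Mapping[str, np.ndarray], ends: Mapping[str, np.ndarray]):
        self.layout = layout
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._offset: dict[str, int] = {}
        offset = 0
        for chrom in layout.chromosomes:
            s = np.asarray(starts[chrom], dtype=np.int64)
            e = np.asarray(ends[chrom], dtype=np.int64)
            if s.size == 0 or s[0] != 0 or e[-1] != layout[chrom]:
                raise ValueError(f"fragments do not tile chromosome {chrom!r}")
            if not (np.all(s < e) and np.all(s[1:] == e[:-1])):
                raise ValueError(f"fragments on {chrom!r} must abut without overlap")
            self._starts[chrom] = s
            self._ends[chrom] = e
            self._offset[chrom] = offset
            offset += s.size
        self._n = offset
        # reverse lookup: global index -> chromosome, via offsets
        self._chrom_order = list(layout.chromosomes)
        self._offsets_arr = np.array([self._offset[c] for c in self._chrom_order], dtype=np.int64)

    def __len__(self) -> int:
        return self._n

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self._chrom_order)

    def starts(self, chrom: str) -> np.ndarray:
        return self._starts[chrom]

    def ends(self, chrom: str) -> np.ndarray:
        return self._ends[chrom]

    def n_fragments(self, chrom: str) -> int:
        return self._starts[chrom].size

    def index_range(self, chrom: str) -> tuple[int, int]:
        """Global [first, last+1) fragment index range of a chromosome."""
        off = self._offset[chrom]
        return off, off + self._starts[chrom].size

    def fragment_at(self, chrom: str, pos: int) -> int:
        """Global index of the fragment containing ``pos`` (0-based)."""
        if not 0 <= pos < self.layout[chrom]:
            raise ValueError(f"position {pos} outside chromosome {chrom!r}")
        local = int(np.searchsorted(self._ends[chrom], pos, side="right"))
        return self._offset[chrom] + local

    def interval(self, index: int) -> tuple[str, int, int]:
        """(chrom, start, end) of the fragment with global ``index``."""
        if not 0 <= index < self._n:
            raise IndexError(f"fragment index {index} out of range")
        ci = int(np.searchsorted(self._offsets_arr, index, side="right")) - 1
        chrom = self._chrom_order[ci]
        local = index - self._offset[chrom]
        return chrom, int(self._starts[chrom][local]), int(self._ends[chrom][local])

    def overlapping(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Global indices of fragments overlapping [start, end) by >= 1 bp."""
        if end <= start:
            return np.empty(0, dtype=np.int64)
        s = self._starts[chrom]
        e = self._ends[chrom]
        lo = int(np.searchsorted(e, start, side="right"))
        hi = int(np.searchsorted(s, end, side="left"))
        return np.arange(lo, hi, dtype=np.int64) + self._offset[chrom]

    def iter_fragments(self) -> Iterator[tuple[int, str, int, int]]:
        for chrom in self._chrom_order:
            off = self._offset[chrom]
            for i, (s, e) in enumerate(zip(self._starts[chrom], self._ends[chrom])):
                yield off + i, chrom, int(s), int(e)

    def lengths(self) -> np.ndarray:
        return np.concatenate([self._ends[c] - self._starts[c] for c in self._chrom_order])

    def to_frame(self) -> pd.DataFrame:
        rows = [(c, s, e, i) for i, c, s, e in self.iter_fragments()]
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "fragment_id"])


def build_fragment_map(layout: GenomeLayout, cut_positions: Mapping[str, Sequence[int]]) -> FragmentMap:
    """Build a fragment map from per-chromosome restriction cut positions.

    Cut positions must be strictly increasing and strictly inside the
    chromosome; a chromosome with k cuts yields k+1 fragments.
    """
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom in layout.chromosomes:
        cuts = np.asarray(cut_positions.get(chrom, ()), dtype=np.int64)
        length = layout[chrom]
        if cuts.size:
            if np.any(np.diff(cuts) <= 0):
                raise ValueError(f"cut positions on {chrom!r} must be strictly increasing")
            if cuts[0] <= 0 or cuts[-1] >= length:
                raise ValueError(f"cut positions on {chrom!r} must lie strictly inside (0, {length})")
        bounds = np.concatenate([[0], cuts, [length]])
        starts[chrom] = bounds[:-1]
        ends[chrom] = bounds[1:]
    return FragmentMap(layout, starts, ends)


class TssCatalog:
    """Per-gene transcription start sites with strand.

    Backed by a DataFrame with columns (gene, chrom, pos, strand); genes may
    carry multiple TSS records, but bait selection operates on deduplicated
    TSSs (see :func:`select_bait_fragments`).
    """

    COLUMNS = ("gene", "chrom", "pos", "strand")

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"TSS catalog missing columns: {sorted(missing)}")
        bad = ~frame["strand"].isin(["+", "-"])
        if bad.any():
            raise ValueError("TSS strand must be '+' or '-'")
        self.frame = (
            frame.loc[:, list(self.COLUMNS)]
            .sort_values(["chrom", "pos", "gene"], kind="mergesort")
            .reset_index(drop=True)
        )
        self._by_gene: dict[str, tuple[str, int, str]] = {}
        for r in self.frame.itertuples():
            self._by_gene.setdefault(r.gene, (r.chrom, int(r.pos), r.strand))
        self._pos_by_chrom: dict[str, np.ndarray] = {}
        self._gene_by_chrom: dict[str, np.ndarray] = {}
        for chrom, grp in self.frame.groupby("chrom", sort=False):
            self._pos_by_chrom[chrom] = grp["pos"].to_numpy(dtype=np.int64)
            self._gene_by_chrom[chrom] = grp["gene"].to_numpy(dtype=object)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.frame["gene"]))

    def tss_of(self, gene: str) -> tuple[str, int, str]:
        """(chrom, pos, strand) of a gene's (first) TSS."""
        return self._by_gene[gene]

    def genes_in(self, chrom: str, start: int, end: int, *, exclude: set[str] | None = None) -> set[str]:
        """Distinct genes with a TSS position in [start, end)."""
        pos = self._pos_by_chrom.get(chrom)
        if pos is None or end <= start:
            return set()
        lo = int(np.searchsorted(pos, start, side="left"))
        hi = int(np.searchsorted(pos, end, side="left"))
        found = set(self._gene_by_chrom[chrom][lo:hi])
        if exclude:
            found -= exclude
        return found

    def validate_against(self, layout: GenomeLayout) -> None:
        for row in self.frame.itertuples():
            if not 0 <= row.pos < layout[row.chrom]:
                raise ValueError(f"TSS for {row.gene} at {row.chrom}:{row.pos} outside chromosome")


@dataclass(frozen=True)
class PromoterRegion:
    """Merged-TSS promoter region: the envelope of a gene's bait fragments.

    Several genes may be annotated to coordinate-identical regions; each gene
    gets its own record so gene-level analyses stay simple.
    """

    genes: tuple[str, ...]
    chrom: str
    start: int
    end: int
    strand: str

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class BaitSet:
    """Captured (bait) restriction fragments per gene, plus probe-end windows.

    ``probes`` holds the 120 bp windows adjacent to the selected cut sites,
    recorded as (gene, chrom, start, end); probe sequence construction is not
    modeled, only fragment/end selection.
    """

    baits: dict[str, tuple[int, ...]]
    probes: list[tuple[str, str, int, int]] = field(default_factory=list)

    def fragments(self) -> set[int]:
        out: set[int] = set()
        for idx in self.baits.values():
            out.update(idx)
        return out

    def genes(self) -> tuple[str, ...]:
        return tuple(self.baits)


def _dedup_tss(catalog: TssCatalog, dedup_dist: int) -> pd.DataFrame:
    """Retain one TSS per 1 kb cluster, keeping the smallest coordinate.

    Greedy left-to-right scan per chromosome: a TSS is retained if it lies at
    least ``dedup_dist`` from the previously retained TSS.
    """
    keep_rows = []
    for chrom, grp in catalog.frame.groupby("chrom", sort=False):
        last = None
        for row in grp.itertuples():
            if last is None or row.pos - last >= dedup_dist:
                keep_rows.append(row)
                last = row.pos
    return pd.DataFrame(keep_rows).loc[:, ["gene", "chrom", "pos", "strand"]]


def select_bait_fragments(
    tss_catalog: TssCatalog,
    fragment_map: FragmentMap,
    *,
    window: int = 10_000,
    min_len: int = 200,
    dedup_dist: int = 1_000,
    n_ends: int = 4,
    probe_len: int = 120,
) -> BaitSet:
    """Select capture bait fragments around each TSS.

    Candidate fragments must be longer than ``min_len`` and overlap the
    ``window`` around a retained TSS (TSSs closer than ``dedup_dist`` are
    deduplicated, smallest coordinate kept). Both cut-site ends of each
    candidate fragment compete, ranked by distance from the cut site to the
    TSS; up to ``n_ends`` ends are selected, with each fragment contributing
    at most one end before any fragment's second end is considered. Ties are
    broken by fragment index, then by the left end.
    """
    retained = _dedup_tss(tss_catalog, dedup_dist)
    baits: dict[str, tuple[int, ...]] = {}
    probes: list[tuple[str, str, int, int]] = []
    for row in retained.itertuples():
        chrom, tss = row.chrom, int(row.pos)
        lo = max(0, tss - window)
        hi = min(fragment_map.layout[chrom], tss + window)
        candidates = []  # (distance, fragment_idx, side, end_pos)
        for idx in fragment_map.overlapping(chrom, lo, hi):
            _, fs, fe = fragment_map.interval(int(idx))
            if fe - fs <= min_len:
                continue
            candidates.append((abs(fs - tss), int(idx), 0, fs))
            candidates.append((abs(fe - tss), int(idx), 1, fe))
        candidates.sort()
        chosen: list[tuple[int, int, int]] = []  # (fragment_idx, side, end_pos)
        used_fragments: set[int] = set()
        for pass_two in (False, True):
            for dist, idx, side, end_pos in candidates:
                if len(chosen) >= n_ends:
                    break
                if (idx, side, end_pos) in {(c[0], c[1], c[2]) for c in chosen}:
                    continue
                if not pass_two and idx in used_fragments:
                    continue
                chosen.append((idx, side, end_pos))
                used_fragments.add(idx)
            if len(chosen) >= n_ends:
                break
        if not chosen:
            logging.getLogger(__name__).warning(
                "no eligible bait fragment for gene %s at %s:%d", row.gene, chrom, tss
            )
            continue
        baits[row.gene] = tuple(sorted({idx for idx, _, _ in chosen}))
        for idx, side, end_pos in chosen:
            if side == 0:  # probe extends into the fragment from its left cut site
                probes.append((row.gene, chrom, end_pos, end_pos + probe_len))
            else:
                probes.append((row.gene, chrom, max(0, end_pos - probe_len), end_pos))
    return BaitSet(baits=baits, probes=probes)


def merge_promoter_regions(baits: BaitSet, tss_catalog: TssCatalog, fragment_map: FragmentMap) -> list[PromoterRegion]:
    """Build merged-TSS promoter regions: per gene, the envelope of its baits.

    Genes whose bait fragments produce coordinate-identical envelopes are
    still reported individually (one record per gene).
    """
    regions: list[PromoterRegion] = []
    for gene, idx in baits.baits.items():
        if not idx:
            continue
        chrom, _, strand = tss_catalog.tss_of(gene)
        starts, ends = [], []
        for i in idx:
            c, s, e = fragment_map.interval(i)
            starts.append(s)
            ends.append(e)
        regions.append(PromoterRegion(genes=(gene,), chrom=chrom, start=min(starts), end=max(ends), strand=strand))
    regions.sort(key=lambda r: (r.chrom, r.start, r.genes))
    return regions
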