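"""Readers and writers for every external format the toolkit touches.

Conventions
-----------
* Internally all coordinates are 0-based, half-open.
* BED and bedGraph files are 0-based half-open (the standard).
* Interaction tables (ibed-like and study-table dialects) and the TSS/eQTL/
  SNP TSV tables are 1-based inclusive on disk and converted at this
  boundary.
* All output tables are tab-separated with a single commented header line.
* Malformed rows raise :class:`FormatError` naming the offending line.

Every reader/writer pair is a lossless round trip on valid data; the tests
enforce this property.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import obonet
import pandas as pd

from .genome import FragmentMap, GenomeLayout, TssCatalog
from .records import ConsensusInteraction, Interaction

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_interactions",
    "write_interactions",
    "read_washu_track",
    "write_washu_track",
    "read_obo_lite",
    "read_gene_associations",
    "read_tss_table",
    "write_tss_table",
    "read_fragment_map_bed",
    "write_fragment_map_bed",
    "read_table",
    "write_table",
]

IBED_COLUMNS = (
    "bait_chr",
    "bait_start",
    "bait_end",
    "bait_name",
    "otherEnd_chr",
    "otherEnd_start",
    "otherEnd_end",
    "otherEnd_name",
    "N_reads",
    "score",
)

# study-table dialect: header names mapped onto the ibed roles; auto-detected
STUDYTABLE_HEADER_MAP = {
    "chr_bait": "bait_chr",
    "start_bait": "bait_start",
    "end_bait": "bait_end",
    "gene": "bait_name",
    "chr": "otherEnd_chr",
    "start": "otherEnd_start",
    "end": "otherEnd_end",
    "name": "otherEnd_name",
    "reads": "N_reads",
    "chicago_score": "score",
}


class FormatError(ValueError):
    """A malformed input row; message carries file and line number."""


def _err(path, lineno: int, msg: str) -> FormatError:
    return FormatError(f"{path}:{lineno}: {msg}")


# ---------------------------------------------------------------------------
# BED / bedGraph


def read_bed(path) -> pd.DataFrame:
    """Read BED (0-based half-open) into (chrom, start, end[, name[, value]])."""
    rows = []
    ncols = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise _err(path, lineno, "BED row needs at least 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise _err(path, lineno, f"non-integer coordinates {parts[1]!r}/{parts[2]!r}") from None
            if end <= start:
                raise _err(path, lineno, f"end {end} <= start {start}")
            extra = parts[3:5]
            rows.append((parts[0], start, end, *extra, *[None] * (2 - len(extra))))
            ncols = max(ncols, min(len(parts), 5))
    columns = ["chrom", "start", "end", "name", "value"]
    frame = pd.DataFrame(rows, columns=columns)
    frame = frame.loc[:, columns[: max(3, ncols)]]
    if "value" in frame.columns:
        frame["value"] = pd.to_numeric(frame["value"], errors="coerce")
    return frame


def write_bed(frame: pd.DataFrame, path) -> None:
    cols = [c for c in ("chrom", "start", "end", "name", "value") if c in frame.columns]
    frame.loc[:, cols].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> pd.DataFrame:
    """Read bedGraph (chrom, start, end, signed value), 0-based half-open."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise _err(path, lineno, "bedGraph row needs 4 columns")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
            except ValueError:
                raise _err(path, lineno, "malformed bedGraph row") from None
            if rows[-1][2] <= rows[-1][1]:
                raise _err(path, lineno, "end <= start")
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def write_bedgraph(frame: pd.DataFrame, path) -> None:
    frame.loc[:, ["chrom", "start", "end", "value"]].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Interaction tables


def _detect_dialect(header: Sequence[str]) -> str:
    if list(header) == list(IBED_COLUMNS):
        return "ibed"
    if set(STUDYTABLE_HEADER_MAP) <= set(header):
        return "studytable"
    raise FormatError(f"cannot detect interaction dialect from header {header!r}")


def read_interactions(
    path,
    dialect: str = "auto",
    *,
    replicate: str = "",
    header_map: Mapping[str, str] | None = None,
) -> list[Interaction]:
    """Read an interaction table (1-based inclusive on disk).

    ``dialect`` is ``"ibed"`` (fixed column order), ``"studytable"`` (columns
    located by header name, remappable via ``header_map``), or ``"auto"``.
    Trans rows are parsed and flagged via ``Interaction.is_cis``; downstream
    stages exclude them.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        return []
    header = lines[0].lstrip("#").split("\t")
    if dialect == "auto":
        dialect = _detect_dialect(header)
    if dialect == "ibed":
        if header != list(IBED_COLUMNS):
            raise FormatError(f"{path}:1: ibed header must be {IBED_COLUMNS}")
        col = {name: i for i, name in enumerate(header)}
    elif dialect == "studytable":
        mapping = dict(STUDYTABLE_HEADER_MAP)
        if header_map:
            mapping.update(header_map)
        col = {}
        for src, role in mapping.items():
            if src not in header:
                raise FormatError(f"{path}:1: study-table header missing column {src!r}")
            col[role] = header.index(src)
    else:
        raise FormatError(f"unknown interaction dialect {dialect!r}")

    records: list[Interaction] = []
    for lineno, line in enumerate(lines[1:], 2):
        if not line.strip():
            continue
        parts = line.split("\t")
        try:
            b_start = int(parts[col["bait_start"]])
            b_end = int(parts[col["bait_end"]])
            o_start = int(parts[col["otherEnd_start"]])
            o_end = int(parts[col["otherEnd_end"]])
            score = float(parts[col["score"]])
        except (ValueError, IndexError):
            raise _err(path, lineno, "malformed interaction row") from None
        if b_end < b_start or o_end < o_start:
            raise _err(path, lineno, f"end before start in interaction row")
        rec = Interaction(
            gene=parts[col["bait_name"]],
            chrom=parts[col["bait_chr"]],
            bait_start=b_start - 1,
            bait_end=b_end,
            other_chrom=parts[col["otherEnd_chr"]],
            other_start=o_start - 1,
            other_end=o_end,
            score=score,
            replicate=replicate,
        )
        records.append(rec)
    return records


def write_interactions(records: Iterable[Interaction], path, *, n_reads: int = 0) -> None:
    """Write ibed dialect (1-based inclusive), one row per record."""
    with open(path, "w") as fh:
        fh.write("\t".join(IBED_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.chrom,
                        r.bait_start + 1,
                        r.bait_end,
                        r.gene,
                        r.other_chrom,
                        r.other_start + 1,
                        r.other_end,
                        ".",
                        n_reads,
                        r.score,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# WashU longrange track


def write_washu_track(interactions: Iterable[ConsensusInteraction | Interaction], path) -> None:
    """Emit interactions as WashU EpiGenome Browser longrange text.

    Format per line: ``chrom  start  end  chrom2:start2-end2,score`` with
    0-based half-open coordinates, sorted by coordinate.
    """
    rows = []
    for it in interactions:
        if isinstance(it, ConsensusInteraction):
            a = (it.chrom, it.promoter_start, it.promoter_end)
            b = (it.chrom, it.distal_start, it.distal_end)
            score = max(it.scores) if it.scores else 0.0
        else:
            a = (it.chrom, it.bait_start, it.bait_end)
            b = (it.other_chrom, it.other_start, it.other_end)
            score = it.score
        rows.append((*a, f"{b[0]}:{b[1]}-{b[2]},{score:g}"))
    rows.sort()
    with open(path, "w") as fh:
        for chrom, start, end, target in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{target}\n")


def read_washu_track(path) -> pd.DataFrame:
    """Parse a longrange file back into paired intervals plus score."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise _err(path, lineno, "longrange row needs 4 columns")
            target, _, score = parts[3].rpartition(",")
            chrom2, _, span = target.partition(":")
            s2, _, e2 = span.partition("-")
            try:
                rows.append(
                    (parts[0], int(parts[1]), int(parts[2]), chrom2, int(s2), int(e2), float(score))
                )
            except ValueError:
                raise _err(path, lineno, "malformed longrange target") from None
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "chrom2", "start2", "end2", "score"]
    )


# ---------------------------------------------------------------------------
# Gene Ontology (OBO subset) and gene associations


def read_obo_lite(path) -> nx.MultiDiGraph:
    """Parse an OBO file into a child->parent (is_a) directed acyclic graph.

    Node attributes keep the term ``name`` when present. Raises on cyclic
    ontologies.
    """
    graph = obonet.read_obo(path)
    if not nx.is_directed_acyclic_graph(graph):
        raise FormatError(f"{path}: ontology graph contains a cycle")
    return graph


def read_gene_associations(path, dag: nx.MultiDiGraph | None = None) -> dict[str, set[str]]:
    """Read a GAF-like two-column TSV (gene <tab> term id) into gene->terms.

    When ``dag`` is given, associations naming terms absent from the ontology
    raise a line-numbered error (orphan term ids).
    """
    assoc: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "!")):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise _err(path, lineno, "association row needs gene and term columns")
            gene, term = parts[0], parts[1]
            if dag is not None and term not in dag:
                raise _err(path, lineno, f"orphan term id {term!r} not in ontology")
            assoc.setdefault(gene, set()).add(term)
    if not assoc:
        raise FormatError(f"{path}: empty gene-association file")
    return assoc


# ---------------------------------------------------------------------------
# TSS catalog / fragment map / generic tables


def read_tss_table(path) -> TssCatalog:
    """Read a TSS catalog TSV (gene, chrom, pos, strand), pos 1-based."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise _err(path, lineno, "TSS row needs (gene, chrom, pos, strand)")
            try:
                pos = int(parts[2])
            except ValueError:
                raise _err(path, lineno, f"non-integer TSS position {parts[2]!r}") from None
            if parts[3] not in ("+", "-"):
                raise _err(path, lineno, f"bad strand {parts[3]!r}")
            rows.append((parts[0], parts[1], pos - 1, parts[3]))
    return TssCatalog(pd.DataFrame(rows, columns=["gene", "chrom", "pos", "strand"]))


def write_tss_table(catalog: TssCatalog, path) -> None:
    frame = catalog.frame.copy()
    frame["pos"] = frame["pos"] + 1
    write_table(frame, path)


def read_fragment_map_bed(path, layout: GenomeLayout) -> FragmentMap:
    """Read a fragment map from BED (chrom, start, end, fragment_id)."""
    frame = read_bed(path)
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom, grp in frame.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        starts[chrom] = grp["start"].to_numpy(dtype=np.int64)
        ends[chrom] = grp["end"].to_numpy(dtype=np.int64)
    return FragmentMap(layout, starts, ends)


def write_fragment_map_bed(fragment_map: FragmentMap, path) -> None:
    with open(path, "w") as fh:
        for idx, chrom, start, end in fragment_map.iter_fragments():
            fh.write(f"{chrom}\t{start}\t{end}\t{idx}\n")


def write_table(frame: pd.DataFrame, path) -> None:
    """Write a TSV with a single '#'-commented header line."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(map(str, frame.columns)) + "\n")
        frame.to_csv(fh, sep="\t", header=False, index=False)


def read_table(path, **kwargs) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` (commented header)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#"):
            raise FormatError(f"{path}:1: expected '#'-commented header")
        names = header.lstrip("#").split("\t")
        frame = pd.read_csv(fh, sep="\t", names=names, **kwargs)
    return frame
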