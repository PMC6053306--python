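"""A/B compartment assignment, switch classification and expression tests.

Compartment calls arrive as a signed-eigenvalue bedGraph (positive = A under
the supplied sign convention) or as labeled BED intervals; the sign
convention is never inferred here — callers must supply a track whose signs
are already oriented. Genes are anchored by their TSS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .genome import TssCatalog

logger = logging.getLogger(__name__)

__all__ = [
    "CompartmentTrack",
    "assign_compartment",
    "classify_switch",
    "switch_expression_test",
    "ab_expression_test",
    "log2fc_from_tpm",
]


@dataclass
class CompartmentTrack:
    """Non-overlapping intervals with an A/B label per interval."""

    frame: pd.DataFrame  # columns: chrom, start, end, label in {A, B}

    def __post_init__(self) -> None:
        if not {"chrom", "start", "end", "label"} <= set(self.frame.columns):
            raise ValueError("compartment track needs (chrom, start, end, label)")
        if not self.frame["label"].isin(["A", "B"]).all():
            raise ValueError("compartment labels must be 'A' or 'B'")
        self.frame = self.frame.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._labels: dict[str, np.ndarray] = {}
        for chrom, grp in self.frame.groupby("chrom", sort=False):
            s = grp["start"].to_numpy(dtype=np.int64)
            e = grp["end"].to_numpy(dtype=np.int64)
            if np.any(s[1:] < e[:-1]):
                raise ValueError(f"compartment intervals overlap on {chrom!r}")
            self._starts[chrom] = s
            self._ends[chrom] = e
            self._labels[chrom] = grp["label"].to_numpy(dtype=object)

    @classmethod
    def from_bedgraph(cls, frame: pd.DataFrame, *, a_is_positive: bool = True) -> "CompartmentTrack":
        """Build from a signed eigenvalue track; sign convention is the caller's."""
        sign = np.sign(frame["value"].to_numpy(dtype=float))
        label = np.where(sign > 0, "A", "B") if a_is_positive else np.where(sign > 0, "B", "A")
        out = frame.loc[sign != 0, ["chrom", "start", "end"]].copy()
        out["label"] = label[sign != 0]
        return cls(out)

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
        """(starts, ends, labels) arrays for one chromosome, if present."""
        if chrom not in self._starts:
            return None
        return self._starts[chrom], self._ends[chrom], self._labels[chrom]

    def label_at(self, chrom: str, pos: int) -> str | None:
        s = self._starts.get(chrom)
        if s is None:
            return None
        i = int(np.searchsorted(s, pos, side="right")) - 1
        if i >= 0 and pos < self._ends[chrom][i]:
            return str(self._labels[chrom][i])
        return None


def assign_compartment(tss_catalog: TssCatalog, track: CompartmentTrack) -> dict[str, str]:
    """Gene -> {'A', 'B', 'unassigned'} by the interval containing its TSS."""
    out: dict[str, str] = {}
    for gene in tss_catalog.genes:
        chrom, pos, _ = tss_catalog.tss_of(gene)
        label = track.label_at(chrom, pos)
        out[gene] = label if label is not None else "unassigned"
    return out


def classify_switch(assign_first: Mapping[str, str], assign_second: Mapping[str, str]) -> dict[str, str]:
    """Cross-tabulate two compartment assignments into switch classes.

    Classes: stable_A, stable_B, A_to_B, B_to_A. Genes unassigned in either
    cell type are excluded.
    """
    classes = {("A", "A"): "stable_A", ("B", "B"): "stable_B", ("A", "B"): "A_to_B", ("B", "A"): "B_to_A"}
    out: dict[str, str] = {}
    for gene, a in assign_first.items():
        b = assign_second.get(gene)
        key = (a, b)
        if key in classes:
            out[gene] = classes[key]
    return out


def log2fc_from_tpm(
    tpm_first: Mapping[str, float], tpm_second: Mapping[str, float], *, pseudocount: float = 1.0
) -> dict[str, float]:
    """Fallback log2 fold change log2((TPM2 + c) / (TPM1 + c)) per gene.

    Meant for when no differential-expression table is available; a proper
    DE log2FC table (e.g. from DESeq2) is preferred when supplied.
    """
    genes = set(tpm_first) & set(tpm_second)
    return {
        g: float(np.log2((tpm_second[g] + pseudocount) / (tpm_first[g] + pseudocount))) for g in sorted(genes)
    }


def switch_expression_test(
    switch_classes: Mapping[str, str], log2fc: Mapping[str, float]
) -> tuple[pd.DataFrame, dict[tuple[str, str], float]]:
    """Per-class log2FC summaries plus pairwise Wilcoxon rank-sum p-values.

    Tests are two-sided with the normal approximation and tie correction,
    run between each switching class and each stable class. Classes with
    fewer than two genes yield NaN.
    """
    values: dict[str, np.ndarray] = {}
    for cls in ("stable_A", "stable_B", "A_to_B", "B_to_A"):
        vals = [log2fc[g] for g, c in switch_classes.items() if c == cls and g in log2fc]
        values[cls] = np.asarray(vals, dtype=float)
    summary = pd.DataFrame(
        {
            "class": list(values),
            "n": [v.size for v in values.values()],
            "median_log2fc": [float(np.median(v)) if v.size else np.nan for v in values.values()],
            "mean_log2fc": [float(np.mean(v)) if v.size else np.nan for v in values.values()],
        }
    )
    pvals: dict[tuple[str, str], float] = {}
    for switching in ("A_to_B", "B_to_A"):
        for stable in ("stable_A", "stable_B"):
            a, b = values[switching], values[stable]
            if a.size < 2 or b.size < 2:
                pvals[(switching, stable)] = float("nan")
                continue
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
            pvals[(switching, stable)] = float(res.pvalue)
    return summary, pvals


def ab_expression_test(
    assignment: Mapping[str, str], expression: Mapping[str, float]
) -> tuple[pd.DataFrame, float]:
    """Compare expression of A- vs B-compartment genes (Wilcoxon rank-sum)."""
    a = np.asarray([expression[g] for g, c in assignment.items() if c == "A" and g in expression], dtype=float)
    b = np.asarray([expression[g] for g, c in assignment.items() if c == "B" and g in expression], dtype=float)
    summary = pd.DataFrame(
        {
            "compartment": ["A", "B"],
            "n": [a.size, b.size],
            "median": [float(np.median(a)) if a.size else np.nan, float(np.median(b)) if b.size else np.nan],
            "mean": [float(np.mean(a)) if a.size else np.nan, float(np.mean(b)) if b.size else np.nan],
        }
    )
    if a.size < 2 or b.size < 2:
        return summary, float("nan")
    return summary, float(stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue)
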