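"""Core interaction record types shared across modules."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Interaction", "ConsensusInteraction"]


@dataclass(frozen=True)
class Interaction:
    """One significant bait->distal contact from a single replicate.

    Coordinates are 0-based half-open. ``gene`` is the merged-TSS annotation
    of the bait end; ``score`` is a CHiCAGO-style non-negative significance
    score (consumed, never computed here). Trans contacts are representable
    (``other_chrom`` differing from ``chrom``) but flagged and excluded from
    all downstream analyses.
    """

    gene: str
    chrom: str
    bait_start: int
    bait_end: int
    other_chrom: str
    other_start: int
    other_end: int
    score: float
    replicate: str = ""

    @property
    def is_cis(self) -> bool:
        return self.chrom == self.other_chrom

    @property
    def span_distance(self) -> float:
        """Midpoint-to-midpoint distance between the two ends (cis only)."""
        if not self.is_cis:
            raise ValueError("span distance undefined for trans contacts")
        return abs((self.bait_start + self.bait_end) / 2.0 - (self.other_start + self.other_end) / 2.0)


@dataclass(frozen=True)
class ConsensusInteraction:
    """A replicate-consensus promoter interaction.

    ``distal_start``/``distal_end`` is the un-extended envelope of the member
    distal fragments; ``replicates`` the supporting replicate labels; scores
    the per-replicate maximum CHiCAGO score.
    """

    gene: str
    chrom: str
    promoter_start: int
    promoter_end: int
    distal_start: int
    distal_end: int
    replicates: tuple[str, ...]
    scores: tuple[float, ...]

    @property
    def support(self) -> int:
        return len(self.replicates)

    @property
    def span_distance(self) -> float:
        return abs(
            (self.promoter_start + self.promoter_end) / 2.0 - (self.distal_start + self.distal_end) / 2.0
        )

    @property
    def promoter_mid(self) -> float:
        return (self.promoter_start + self.promoter_end) / 2.0

    @property
    def distal_mid(self) -> float:
        return (self.distal_start + self.distal_end) / 2.0
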