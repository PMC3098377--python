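"""Genomic coordinate primitives.

All coordinates are 0-based, half-open (`[start, end)`), matching BED on disk.
"""
from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GenomicInterval:
    """A chromosome span with optional strand; the universal coordinate currency."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of shared bases (0 if different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass
class GeneModel:
    """A gene body with strand-aware TSS/TES accessors.

    For a ``+`` gene the TSS is ``start`` and the TES ``end - 1``; for a ``-``
    gene the TSS is ``end - 1`` and the TES ``start``.
    """

    chrom: str
    start: int
    end: int
    strand: str
    name: str
    expressed: bool = False

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class CpGIsland:
    """A predicted or simulated CpG island.

    assoc is one of {"TSS", "TES", "other"}: whether the island overlaps a
    transcription start site window, a transcription end site window, or
    neither (TSS takes precedence).
    """

    interval: GenomicInterval
    gc: float
    oe: float
    assoc: str = "other"
    name: str = ""
    strength: str = ""
    methylation: str = "none"  # none | full | imprinted_50_50 (simulated truth only)

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    def __len__(self) -> int:
        return len(self.interval)


def merge_intervals(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or touching half-open spans; returns sorted spans."""
    if not spans:
        return []
    spans = sorted(spans)
    merged = [list(spans[0])]
    for s, e in spans[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]
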