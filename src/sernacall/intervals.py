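"""Genomic interval primitives shared by every pipeline stage.

All coordinates are 0-based half-open (BED convention): an interval
``chrom:start-end`` covers bases ``start .. end-1``.  Strand is ignored
throughout — enhancer transcription is bidirectional and no operation in
this package is strand-aware.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "GenomicInterval",
    "EnhancerLocus",
    "GeneLocus",
    "parse_locus_id",
    "interval_gap",
]

_LOCUS_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def midpoint(self) -> int:
        """Integer midpoint, ``floor((start + end) / 2)``; always in [start, end)."""
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def parse_locus_id(locus_id: str) -> GenomicInterval:
    """Parse a ``"chrom:start-end"`` key into a :class:`GenomicInterval`.

    Raises ``ValueError`` on malformed keys or empty intervals.
    """
    m = _LOCUS_RE.match(locus_id)
    if m is None:
        raise ValueError(f"malformed locus key {locus_id!r}; expected 'chrom:start-end'")
    return GenomicInterval(m["chrom"], int(m["start"]), int(m["end"]))


@dataclass(frozen=True)
class EnhancerLocus:
    """An enhancer interval keyed by its ``chrom:start-end`` identifier."""

    interval: GenomicInterval
    id: str = field(default="")

    def __post_init__(self) -> None:
        if not self.id:
            object.__setattr__(self, "id", self.interval.id)

    @classmethod
    def from_id(cls, locus_id: str) -> "EnhancerLocus":
        return cls(parse_locus_id(locus_id), locus_id)

    @property
    def midpoint(self) -> int:
        return self.interval.midpoint


@dataclass(frozen=True)
class GeneLocus:
    """A gene body interval with its (HGNC-style) symbol.

    Multiple loci may share a symbol (alternative assemblies, paralogous
    annotations); callers must not assume symbol uniqueness.
    """

    symbol: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("gene symbol must be non-empty")


def interval_gap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Gap in bp between the closest ends of two same-chromosome intervals.

    Zero when the intervals overlap or abut base-to-base.  Raises on
    different chromosomes — a cross-chromosome distance is undefined here.
    """
    if a.chrom != b.chrom:
        raise ValueError(f"intervals on different chromosomes: {a.chrom} vs {b.chrom}")
    if a.start < b.end and b.start < a.end:
        return 0
    if a.end <= b.start:
        return b.start - a.end
    return a.start - b.end
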