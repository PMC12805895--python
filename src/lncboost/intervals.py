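"""Strand-aware genomic intervals.

All internal coordinates are 0-based half-open ``[start, end)``. GTF I/O
converts from/to the 1-based closed convention at the boundary; BED-style
inputs are already native.
"""

from __future__ import annotations

from dataclasses import dataclass

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open coordinate span on one strand of one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two spans share at least one base (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def upstream_window(
    span: GenomicInterval, window_bp: int = 500, chrom_length: int | None = None
) -> GenomicInterval | None:
    """Window immediately 5' of a span, strand-aware, clipped at chromosome ends.

    For "+" (and unstranded) spans this is ``[start - window, start)``; for "-"
    spans ``[end, end + window)``. Returns None when clipping leaves nothing
    (span starting at position 0 on the plus strand).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if span.strand == "-":
        end = span.end + window_bp
        if chrom_length is not None:
            end = min(end, chrom_length)
        if end <= span.end:
            return None
        return GenomicInterval(span.chrom, span.end, end, "-")
    start = max(0, span.start - window_bp)
    if start >= span.start:
        return None
    return GenomicInterval(span.chrom, start, span.start, span.strand)
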