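"""Genomic signal and interval tracks and their span statistics.

Signal tracks follow bedGraph semantics — a piecewise-constant value over
non-overlapping intervals, absent positions reading 0. Interval tracks are
plain interval sets, optionally labelled per regulator (ReMap peak sets,
JASPAR binding-site annotations). All statistics are computed over the
per-base value vector across the query span by interval arithmetic; the
per-base expansion is the defining semantics (and the test oracle).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ..intervals import GenomicInterval

logger = logging.getLogger(__name__)


@dataclass
class SignalTrack:
    """Piecewise-constant numeric signal, per chromosome."""

    name: str
    signed: bool = False
    _chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict, repr=False
    )

    def add_chrom(self, chrom: str, starts, ends, values) -> None:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        values = np.asarray(values, dtype=np.float64)
        order = np.argsort(starts, kind="stable")
        starts, ends, values = starts[order], ends[order], values[order]
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"track {self.name}: overlapping intervals on {chrom}")
        if not np.all(np.isfinite(values)):
            raise ValueError(f"track {self.name}: non-finite values on {chrom}")
        self._chroms[chrom] = (starts, ends, values)

    def chrom_data(self, chrom: str):
        return self._chroms.get(chrom)

    @property
    def chroms(self) -> list[str]:
        return list(self._chroms)


@dataclass
class IntervalTrack:
    """Interval set, each interval optionally carrying a regulator label."""

    name: str
    intervals: list[GenomicInterval] = field(default_factory=list)
    labels: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.labels and len(self.labels) != len(self.intervals):
            raise ValueError("labels must align with intervals")
        if not self.labels:
            self.labels = [None] * len(self.intervals)

    def add(self, iv: GenomicInterval, label: str | None = None) -> None:
        self.intervals.append(iv)
        self.labels.append(label)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_bedgraph(path: str | Path, name: str | None = None,
                  signed: bool = False, negate: bool = False) -> SignalTrack:
    """Load a bedGraph file (chrom, start, end, value; 0-based half-open).

    ``negate`` flips the sign on load — used for minus-strand signal supplied
    unsigned, so that minus-strand statistics carry their conventional sign.
    """
    path = Path(path)
    track = SignalTrack(name=name or path.stem, signed=signed or negate)
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, value = line.split()[:4]
            v = float(value)
            per_chrom.setdefault(chrom, []).append(
                (int(start), int(end), -v if negate else v)
            )
    for chrom, rows in per_chrom.items():
        starts, ends, values = zip(*rows)
        track.add_chrom(chrom, starts, ends, values)
    return track


def read_bed(path: str | Path, name: str | None = None,
             label_column: int | None = 3) -> IntervalTrack:
    """Load BED intervals; column 4 (the BED name field) is the regulator label."""
    path = Path(path)
    track = IntervalTrack(name=name or path.stem)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            label = None
            if label_column is not None and len(fields) > label_column:
                label = fields[label_column]
            track.add(GenomicInterval(chrom, start, end, strand), label)
    return track


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

ZERO_STATS = {"cov": 0.0, "mean": 0.0, "max": 0.0, "min": 0.0, "sum": 0.0, "std": 0.0}


def signal_stats(track: SignalTrack, span: GenomicInterval) -> dict[str, float]:
    """Summary statistics of a signal over a span.

    The statistics are those of the per-base value vector across the whole
    span, with uncovered bases reading 0: ``cov`` is the fraction of span
    bases with nonzero signal, ``sum`` the per-base total, ``mean``/``std``
    population moments over all span bases, and ``max``/``min`` extrema over
    all span bases (hence 0 participates whenever any base is uncovered).
    A chromosome absent from the track yields all-zero statistics.
    """
    data = track.chrom_data(span.chrom)
    n = len(span)
    if data is None:
        logger.warning(
            "track %s has no data for chromosome %s; zero statistics",
            track.name, span.chrom,
        )
        return dict(ZERO_STATS)
    starts, ends, values = data
    lo = np.searchsorted(ends, span.start, side="right")
    hi = np.searchsorted(starts, span.end, side="left")
    if lo >= hi:
        return dict(ZERO_STATS)
    s = np.maximum(starts[lo:hi], span.start)
    e = np.minimum(ends[lo:hi], span.end)
    w = (e - s).astype(np.float64)
    v = values[lo:hi]
    covered = float(w.sum())
    uncovered = n - covered
    nonzero = float(w[v != 0].sum())
    total = float(np.dot(w, v))
    mean = total / n
    # centred second moment avoids cancellation for near-constant signal
    var = (float(np.dot(w, (v - mean) ** 2)) + uncovered * mean * mean) / n
    vmax = float(v.max())
    vmin = float(v.min())
    if uncovered > 0:
        vmax = max(vmax, 0.0)
        vmin = min(vmin, 0.0)
    return {
        "cov": nonzero / n,
        "mean": mean,
        "max": vmax,
        "min": vmin,
        "sum": total,
        "std": float(np.sqrt(var)),
    }


def _union_overlap(intervals: Iterable[GenomicInterval], span: GenomicInterval) -> int:
    clipped = sorted(
        (max(iv.start, span.start), min(iv.end, span.end))
        for iv in intervals
        if iv.chrom == span.chrom and iv.start < span.end and iv.end > span.start
    )
    total = 0
    cur_s: int | None = None
    cur_e = 0
    for s, e in clipped:
        if cur_s is None:
            cur_s, cur_e = s, e
        elif s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
    if cur_s is not None:
        total += cur_e - cur_s
    return total


def overlap_fraction(track: IntervalTrack, span: GenomicInterval) -> float:
    """Fraction of the span covered by the union of the track's intervals."""
    return _union_overlap(track.intervals, span) / len(span)


def boolean_overlap(
    track: IntervalTrack, span: GenomicInterval, vocabulary: Sequence[str]
) -> np.ndarray:
    """0/1 vector over a regulator vocabulary: 1 iff any interval with that
    label intersects the span by at least one base. Labels outside the
    vocabulary are ignored with a logged warning."""
    index = {name: i for i, name in enumerate(vocabulary)}
    out = np.zeros(len(vocabulary), dtype=np.int8)
    warned: set[str] = set()
    for iv, label in zip(track.intervals, track.labels):
        if label is None:
            continue
        i = index.get(label)
        if i is None:
            if label not in warned:
                logger.warning(
                    "track %s: label %r outside vocabulary; ignored",
                    track.name, label,
                )
                warned.add(label)
            continue
        if out[i]:
            continue
        if iv.overlaps(span):
            out[i] = 1
    return out
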