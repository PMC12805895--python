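"""Barcode-driven FASTQ demultiplexing into per-cluster files.

Single-cell clustering tools export, per cell cluster, a whitelist of cell
barcodes. This module scans the original FASTQ files and groups every read
whose header contains one of a cluster's barcodes into that cluster's
output FASTQ, so cluster-specific reads can be re-aligned or re-assembled
downstream. Matching is substring containment in the header line by
default, exactly mirroring how droplet protocols embed the barcode in the
read name; a strict mode restricts matching to delimited header tokens.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

_GZIP_MAGIC = b"\x1f\x8b"


@dataclass
class BarcodeSet:
    """A cluster label plus its fixed-length barcode whitelist."""

    name: str
    barcodes: frozenset[str]

    def __post_init__(self) -> None:
        lengths = {len(b) for b in self.barcodes}
        if len(lengths) > 1:
            raise ValueError(
                f"barcode set {self.name!r}: mixed barcode lengths {sorted(lengths)}"
            )


@dataclass
class ReadRecord:
    header: str
    sequence: str
    plus: str
    quality: str

    def lines(self) -> str:
        return f"{self.header}\n{self.sequence}\n{self.plus}\n{self.quality}\n"


class FastqFormatError(ValueError):
    pass


def load_barcodes(path: str | Path, name: str | None = None,
                  strip_suffix: bool = False) -> BarcodeSet:
    """Read a plain-text barcode list (one per line).

    Whitespace is stripped; duplicates are removed with a logged count;
    ``strip_suffix`` removes a trailing ``-<digits>`` well-known suffix
    (e.g. the "-1" GEM-well suffix). Empty files and mixed barcode lengths
    are errors.
    """
    path = Path(path)
    raw = [line.strip() for line in path.read_text().splitlines()]
    raw = [b for b in raw if b]
    if not raw:
        raise ValueError(f"{path}: no barcodes found")
    if strip_suffix:
        cleaned = []
        for b in raw:
            head, dash, tail = b.rpartition("-")
            cleaned.append(head if dash and tail.isdigit() else b)
        raw = cleaned
    unique = frozenset(raw)
    dupes = len(raw) - len(unique)
    if dupes:
        logger.warning("%s: removed %d duplicate barcode(s)", path.name, dupes)
    return BarcodeSet(name=name or path.stem, barcodes=unique)


def _open_auto(path: Path):
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == _GZIP_MAGIC:
        return gzip.open(path, "rt")
    return open(path, "rt")


def iter_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream FASTQ records; truncated records raise, naming the index."""
    path = Path(path)
    with _open_auto(path) as fh:
        record_index = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lines = [header, fh.readline(), fh.readline(), fh.readline()]
            if any(not l for l in lines):
                raise FastqFormatError(
                    f"{path.name}: truncated FASTQ record at index {record_index}"
                )
            header, seq, plus, qual = (l.rstrip("\n") for l in lines)
            if not header.startswith("@") or not plus.startswith("+"):
                raise FastqFormatError(
                    f"{path.name}: malformed FASTQ record at index {record_index}"
                )
            if len(seq) != len(qual):
                raise FastqFormatError(
                    f"{path.name}: sequence/quality length mismatch at index "
                    f"{record_index}"
                )
            yield ReadRecord(header, seq, plus, qual)
            record_index += 1


def _header_tokens(header: str) -> set[str]:
    tokens: set[str] = set()
    for field_ in header[1:].split():
        tokens.add(field_)
        tokens.update(field_.split(":"))
    return tokens


@dataclass
class DemuxSummary:
    reads_scanned: int = 0
    matched: dict[str, int] = field(default_factory=dict)
    unmatched: int = 0

    def to_tsv(self) -> str:
        lines = ["category\tcount", f"reads_scanned\t{self.reads_scanned}"]
        for name in sorted(self.matched):
            lines.append(f"matched_{name}\t{self.matched[name]}")
        lines.append(f"unmatched\t{self.unmatched}")
        return "\n".join(lines) + "\n"


def demultiplex(
    fastq_paths: Sequence[str | Path],
    barcode_sets: Iterable[BarcodeSet],
    out_dir: str | Path,
    strict: bool = False,
) -> DemuxSummary:
    """Group reads into per-cluster FASTQ files by header barcode matching.

    A read belongs to set S iff its header contains any barcode of S as a
    substring (``strict=True``: as a whole colon/whitespace-delimited
    token). Reads matching several sets are written to each matching output;
    within each output the input read order is preserved and records are
    byte-identical copies. Returns per-set matched counts plus the unmatched
    total.
    """
    sets = list(barcode_sets)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = DemuxSummary(matched={s.name: 0 for s in sets})
    handles = {s.name: open(out_dir / f"{s.name}.fastq", "w") for s in sets}
    try:
        for path in fastq_paths:
            for record in iter_fastq(path):
                summary.reads_scanned += 1
                tokens = _header_tokens(record.header) if strict else None
                hit = False
                for s in sets:
                    if strict:
                        matched = any(b in tokens for b in s.barcodes)
                    else:
                        matched = any(b in record.header for b in s.barcodes)
                    if matched:
                        handles[s.name].write(record.lines())
                        summary.matched[s.name] += 1
                        hit = True
                if not hit:
                    summary.unmatched += 1
    finally:
        for fh in handles.values():
            fh.close()
    (out_dir / "summary.tsv").write_text(summary.to_tsv())
    return summary
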