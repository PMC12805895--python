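"""Transcript catalogues: annotation I/O, novelty flagging and subclassing.

Reads reference and assembled (StringTie/Cuffcompare-style) GTF files into
:class:`TranscriptModel` records, flags novel transcripts by their generated
IDs, assigns each novel candidate a noncoding subclass (lincRNA / intronic /
antisense / other), extracts spliced sequences from an indexed genome, and
applies the small-RNA exclusion and ncRNA labelling rules used to build the
training corpus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

SMALL_RNA_BIOTYPES = frozenset({"trna", "rrna", "srna"})
NCRNA_BIOTYPE = "ncRNA"
DEFAULT_GENERATED_PREFIX = "MSTRG."

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class NoncodingSubclass(str, Enum):
    """Positional category of a novel noncoding candidate."""

    LINCRNA = "lincRNA"
    INTRONIC = "intronic"
    ANTISENSE = "antisense"
    OTHER = "other"


class GtfParseError(ValueError):
    """Raised for a malformed GTF line; message names the line number."""


@dataclass
class TranscriptModel:
    """An exon chain plus identifiers and provenance attributes."""

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    biotype: str = ""
    ref_gene_id: str | None = None
    class_code: str | None = None
    fpkm: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id}: no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(
                f"transcript {self.transcript_id}: exons span multiple "
                "chromosomes or strands"
            )
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        """Genomic span from first exon start to last exon end."""
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def introns(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
            if b.start > a.end
        ]


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------

def _parse_attributes(raw: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            continue
        key, value = parts
        attrs[key] = value.strip().strip('"')
    return attrs


def parse_annotation(path: str | Path, dialect: str = "reference") -> list[TranscriptModel]:
    """Read a GTF file into transcript models.

    GTF coordinates (1-based closed) are converted to the internal 0-based
    half-open convention. Exon rows are grouped by ``transcript_id``;
    ``ref_gene_id``, ``class_code``, ``gene_biotype``/``biotype`` and
    per-sample ``FPKM_<sample>`` attributes are captured when present and
    unknown attributes are ignored. Transcripts without any exon row are
    rejected and logged, not returned.

    Parameters
    ----------
    path:
        GTF file path.
    dialect:
        "reference" or "assembled"; informational only — both dialects share
        one grammar, assembled files simply carry the Cuffcompare attributes.
    """
    if dialect not in ("reference", "assembled"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, dict[str, str]] = {}
    fpkm: dict[str, dict[str, float]] = {}
    seen: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path.name}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, raw = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(
                    f"{path.name}:{lineno}: non-integer coordinates"
                ) from exc
            if start1 < 1 or end1 < start1:
                raise GtfParseError(
                    f"{path.name}:{lineno}: invalid coordinates {start1}..{end1}"
                )
            attrs = _parse_attributes(raw)
            tid = attrs.get("transcript_id")
            if tid is None:
                if feature == "gene":
                    continue
                raise GtfParseError(f"{path.name}:{lineno}: missing transcript_id")
            if tid not in meta:
                meta[tid] = attrs
                seen.append(tid)
            else:
                for k, v in attrs.items():
                    meta[tid].setdefault(k, v)
            for key, value in attrs.items():
                if key.startswith("FPKM_"):
                    try:
                        fpkm.setdefault(tid, {})[key[5:]] = float(value)
                    except ValueError:
                        pass
                elif key == "FPKM":
                    try:
                        fpkm.setdefault(tid, {})["FPKM"] = float(value)
                    except ValueError:
                        pass
            if feature == "exon":
                if strand not in ("+", "-", "."):
                    raise GtfParseError(
                        f"{path.name}:{lineno}: invalid strand {strand!r}"
                    )
                exons.setdefault(tid, []).append(
                    GenomicInterval(chrom, start1 - 1, end1, strand)
                )

    models: list[TranscriptModel] = []
    for tid in seen:
        if tid not in exons:
            logger.warning("transcript %s has no exon rows; record rejected", tid)
            continue
        attrs = meta[tid]
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=attrs.get("gene_id", tid),
                exons=exons[tid],
                biotype=attrs.get("gene_biotype", attrs.get("biotype", "")),
                ref_gene_id=attrs.get("ref_gene_id"),
                class_code=attrs.get("class_code"),
                fpkm=fpkm.get(tid, {}),
            )
        )
    return models


def write_annotation(models: Sequence[TranscriptModel], path: str | Path,
                     source: str = "lncboost") -> None:
    """Write transcript models as GTF (1-based closed), one exon row per exon."""
    with open(path, "w") as fh:
        for t in models:
            attrs = [f'gene_id "{t.gene_id}"', f'transcript_id "{t.transcript_id}"']
            if t.biotype:
                attrs.append(f'gene_biotype "{t.biotype}"')
            if t.ref_gene_id is not None:
                attrs.append(f'ref_gene_id "{t.ref_gene_id}"')
            if t.class_code is not None:
                attrs.append(f'class_code "{t.class_code}"')
            for sample, value in sorted(t.fpkm.items()):
                attrs.append(f'FPKM_{sample} "{value:g}"')
            raw = "; ".join(attrs) + ";"
            span = t.span
            fh.write(
                "\t".join(
                    [t.chrom, source, "transcript", str(span.start + 1),
                     str(span.end), ".", t.strand, ".", raw]
                )
                + "\n"
            )
            for e in t.exons:
                fh.write(
                    "\t".join(
                        [t.chrom, source, "exon", str(e.start + 1), str(e.end),
                         ".", t.strand, ".", raw]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Novelty and subclassing
# ---------------------------------------------------------------------------

def flag_novel(
    transcripts: Iterable[TranscriptModel],
    generated_prefix: str = DEFAULT_GENERATED_PREFIX,
) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    """Partition transcripts into (novel, annotated).

    A transcript is novel iff its gene_id (or, failing that, transcript_id)
    carries the assembler-generated prefix AND it has no ref_gene_id linking
    it to an annotated gene. The partition is exhaustive and disjoint.
    """
    novel: list[TranscriptModel] = []
    annotated: list[TranscriptModel] = []
    for t in transcripts:
        generated = t.gene_id.startswith(generated_prefix) or t.transcript_id.startswith(
            generated_prefix
        )
        (novel if generated and t.ref_gene_id is None else annotated).append(t)
    return novel, annotated


_CLASS_CODE_MAP = {
    "u": NoncodingSubclass.LINCRNA,
    "i": NoncodingSubclass.INTRONIC,
    "x": NoncodingSubclass.ANTISENSE,
}


def subclass_noncoding(
    novel: TranscriptModel, reference: Sequence[TranscriptModel]
) -> NoncodingSubclass:
    """Assign a positional noncoding subclass to a novel transcript.

    When a Cuffcompare class code is present it takes precedence (u -> lincRNA,
    i -> intronic, x -> antisense); otherwise geometry decides: intronic if the
    candidate's span lies fully inside an intron of a reference transcript (any
    strand), antisense if any exon overlaps a reference exon on the opposite
    strand, lincRNA if it overlaps nothing, and other for remaining exonic
    same-strand overlaps. Ties resolve intronic > antisense > lincRNA.
    """
    if novel.class_code is not None:
        mapped = _CLASS_CODE_MAP.get(novel.class_code)
        if mapped is not None:
            return mapped
        return NoncodingSubclass.OTHER

    span = novel.span
    any_overlap = False
    antisense = False
    for ref in reference:
        if ref.chrom != span.chrom:
            continue
        if not span.overlaps(ref.span):
            continue
        for intron in ref.introns():
            if intron.contains(span):
                return NoncodingSubclass.INTRONIC
        for e in novel.exons:
            for re_ in ref.exons:
                if e.overlaps(re_):
                    any_overlap = True
                    if ref.strand != novel.strand and "." not in (
                        ref.strand, novel.strand
                    ):
                        antisense = True
        # span overlap without exon overlap still counts as proximity
        any_overlap = True
    if antisense:
        return NoncodingSubclass.ANTISENSE
    if not any_overlap:
        return NoncodingSubclass.LINCRNA
    return NoncodingSubclass.OTHER


# ---------------------------------------------------------------------------
# Sequence extraction and training-set rules
# ---------------------------------------------------------------------------

def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_sequence(t: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Spliced, strand-corrected, uppercase transcript sequence.

    ``genome`` is any mapping chrom -> sequence string (a ``pyfaidx.Fasta``
    works via its string slices, as does a plain dict). Exon sequences are
    concatenated in genomic order and reverse-complemented for minus-strand
    transcripts. Soft-masked lowercase bases are uppercased.
    """
    try:
        chrom_seq = genome[t.chrom]
    except KeyError as exc:
        raise KeyError(f"chromosome {t.chrom} absent from genome") from exc
    chrom_len = len(chrom_seq)
    parts: list[str] = []
    for e in t.exons:
        if e.end > chrom_len:
            raise IndexError(
                f"exon [{e.start},{e.end}) beyond end of {t.chrom} ({chrom_len} bp)"
            )
        parts.append(str(chrom_seq[e.start : e.end]))
    seq = "".join(parts).upper()
    if t.strand == "-":
        seq = reverse_complement(seq)
    return seq


def exclude_small_rna(transcripts: Iterable[TranscriptModel]) -> list[TranscriptModel]:
    """Drop tRNA / rRNA / sRNA records (case-insensitive), preserving order."""
    return [t for t in transcripts if t.biotype.lower() not in SMALL_RNA_BIOTYPES]


def assign_labels(transcripts: Sequence[TranscriptModel]) -> list[int]:
    """Binary training labels: 1 iff biotype == "ncRNA", else 0."""
    return [1 if t.biotype == NCRNA_BIOTYPE else 0 for t in transcripts]
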