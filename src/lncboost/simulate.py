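"""Synthetic genomes, annotations, evidence tracks, assemblies and reads.

Every generator is a pure function of its config (one seeded PRNG, no
global state), so outputs are byte-identical across runs and platforms.
The simulated corpus mirrors the statistical structure the classifier
assumes: protein-coding genes carry higher GC content, stronger RNA
polymerase II / H3K4me3 / CAGE signal, denser regulator binding and higher
conservation than noncoding genes, with each shift controlled by an
explicit effect-size knob (zero knobs give class-identical distributions).
Alongside the full genomic path, a direct feature-space simulator provides
labelled matrices with planted informative features for fast model tests.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import TranscriptModel, write_annotation
from .features.matrix import TrackSet
from .features.tracks import IntervalTrack, SignalTrack
from .intervals import GenomicInterval
from .model import LabeledDataset

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the synthetic corpus; defaults define the study conditions."""

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 160_000
    n_pcg: int = 60
    n_ncg: int = 40
    n_small_rna: int = 6
    background_gc: float = 0.40
    # class effect sizes (protein-coding shifted up; 0 = null)
    gc_shift: float = 0.10
    pol2_effect: float = 2.0
    h3k4me3_effect: float = 2.0
    tss_effect: float = 1.5
    cons_effect: float = 0.30
    remap_effect: float = 0.35
    promoter_effect: float = 0.5
    # regulator vocabularies for labelled peak tracks
    n_remap_regulators: int = 12
    n_jaspar_regulators: int = 6
    # assembled-transcriptome fixture
    n_novel: int = 30
    n_samples: int = 2
    # barcoded-read fixture
    n_clusters: int = 2
    n_cells_per_cluster: int = 20
    barcode_length: int = 16
    n_reads: int = 600
    read_length: int = 50
    unassigned_fraction: float = 0.15

    def null_effects(self) -> "FixtureConfig":
        """Copy with every class effect set to zero (the no-signal control)."""
        return replace(
            self, gc_shift=0.0, pol2_effect=0.0, h3k4me3_effect=0.0,
            tss_effect=0.0, cons_effect=0.0, remap_effect=0.0,
            promoter_effect=0.0,
        )


@dataclass
class FixtureTruth:
    """Ground truth recorded by the generators, for recovery checks."""

    labels: dict[str, int] = field(default_factory=dict)
    biotypes: dict[str, str] = field(default_factory=dict)
    subclasses: dict[str, str] = field(default_factory=dict)
    planted_features: list[str] = field(default_factory=list)
    cluster_read_counts: dict[str, int] = field(default_factory=dict)
    cluster_barcodes: dict[str, list[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# reference genome + annotation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=length, p=p)


def make_reference(
    config: FixtureConfig,
) -> tuple[dict[str, str], list[TranscriptModel], FixtureTruth]:
    """Simulate a genome and its annotation.

    Genes are placed non-overlapping left to right with random gaps. Coding
    and noncoding genes share one exon-architecture distribution (1-3 exons,
    introns wide enough to host intronic candidates); only the effect-size
    knobs differentiate the classes — protein-coding exons get GC elevated
    by ``gc_shift``, and the track generator applies the signal shifts.
    Small-RNA genes are single short exons.
    """
    rng = np.random.default_rng(config.seed)
    chroms = {
        f"chr{i + 1}": _random_seq(rng, config.chrom_length, config.background_gc)
        for i in range(config.n_chromosomes)
    }
    small_types = ["tRNA", "rRNA", "sRNA"]
    biotypes = (
        ["protein_coding"] * config.n_pcg
        + ["ncRNA"] * config.n_ncg
        + [small_types[i % 3] for i in range(config.n_small_rna)]
    )
    rng.shuffle(biotypes)

    truth = FixtureTruth()
    transcripts: list[TranscriptModel] = []
    chrom_names = list(chroms)
    cursor = {c: 600 for c in chrom_names}
    ci = 0
    for g, biotype in enumerate(biotypes):
        placed = False
        for _ in range(len(chrom_names)):
            chrom = chrom_names[ci % len(chrom_names)]
            ci += 1
            start = cursor[chrom] + int(rng.integers(300, 900))
            # identical architecture for coding and noncoding genes: class
            # signal comes only from the effect-size knobs, never geometry
            n_exons = 1 if biotype in ("tRNA", "rRNA", "sRNA") else int(
                rng.integers(1, 4)
            )
            exon_lens = rng.integers(150, 400, size=n_exons)
            intron_lens = rng.integers(500, 900, size=max(n_exons - 1, 0))
            if biotype in ("tRNA", "rRNA", "sRNA"):
                exon_lens = rng.integers(60, 120, size=1)
            strand = "+" if rng.random() < 0.5 else "-"
            exons = []
            pos = start
            for e in range(n_exons):
                exons.append(
                    GenomicInterval(chrom, pos, pos + int(exon_lens[e]), strand)
                )
                pos += int(exon_lens[e])
                if e < n_exons - 1:
                    pos += int(intron_lens[e])
            if pos + 600 > config.chrom_length:
                continue
            cursor[chrom] = pos
            placed = True
            break
        if not placed:
            raise ValueError(
                "infeasible placement: chromosomes too short for requested genes"
            )
        gid = f"FBgn{g:07d}"
        tid = f"FBtr{g:07d}"
        gc = config.background_gc + (
            config.gc_shift if biotype == "protein_coding" else 0.0
        )
        arr = chroms[exons[0].chrom]
        for e in exons:
            arr[e.start : e.end] = _random_seq(rng, len(e), gc)
        transcripts.append(
            TranscriptModel(
                transcript_id=tid, gene_id=gid, exons=exons, biotype=biotype
            )
        )
        truth.biotypes[tid] = biotype
        truth.labels[tid] = 1 if biotype == "ncRNA" else 0
    genome = {c: "".join(a) for c, a in chroms.items()}
    return genome, transcripts, truth


# ---------------------------------------------------------------------------
# evidence tracks
# ---------------------------------------------------------------------------

def _add_intervals(
    bucket: dict[str, list[tuple[int, int, float]]], chrom: str,
    start: int, end: int, value: float,
) -> None:
    if end > start and value != 0:
        bucket.setdefault(chrom, []).append((start, end, value))


def _finish_signal(name: str, bucket: dict[str, list[tuple[int, int, float]]],
                   signed: bool = False) -> SignalTrack:
    track = SignalTrack(name=name, signed=signed)
    for chrom, rows in bucket.items():
        rows.sort()
        starts, ends, values = zip(*rows)
        track.add_chrom(chrom, starts, ends, values)
    return track


def make_tracks(
    genome: dict[str, str],
    transcripts: Sequence[TranscriptModel],
    config: FixtureConfig,
) -> TrackSet:
    """Simulate the evidence tracks over an annotated genome.

    Signals are emitted per gene span: Pol II and H3K4me3 blocks covering a
    random sub-span, conservation blocks, and a strand-matched CAGE peak at
    the transcription start site (minus-strand CAGE carries negative
    values). Labelled ReMap/JASPAR peaks are dropped per regulator with a
    class-dependent hit probability; promoter (EPDnew-style) intervals land
    in the upstream window with class-dependent probability.
    """
    rng = np.random.default_rng(config.seed + 1)
    remap_vocab = [f"TF{i:03d}" for i in range(config.n_remap_regulators)]
    jaspar_vocab = [f"MA{i:04d}" for i in range(config.n_jaspar_regulators)]

    pol2: dict[str, list] = {}
    h3k: dict[str, list] = {}
    tss_p: dict[str, list] = {}
    tss_m: dict[str, list] = {}
    cons_a: dict[str, list] = {}
    cons_b: dict[str, list] = {}
    remap = IntervalTrack(name="remap")
    jaspar = IntervalTrack(name="jaspar")
    epdnew = IntervalTrack(name="epdnew")

    base_hit = 0.25
    for t in transcripts:
        span = t.span
        pcg = 1.0 if t.biotype == "protein_coding" else 0.0
        n = len(span)

        if rng.random() < 0.85:
            frac = rng.uniform(0.3, 0.9)
            v = rng.gamma(2.0, 1.0) * (1.0 + config.pol2_effect * pcg)
            _add_intervals(pol2, span.chrom, span.start,
                           span.start + int(frac * n), v)
        if rng.random() < 0.85:
            frac = rng.uniform(0.3, 0.9)
            v = rng.gamma(2.0, 1.0) * (1.0 + config.h3k4me3_effect * pcg)
            _add_intervals(h3k, span.chrom, span.end - int(frac * n), span.end, v)
        # strand-matched CAGE peak at the TSS
        v = rng.gamma(2.0, 1.0) * (1.0 + config.tss_effect * pcg)
        if t.strand == "-":
            _add_intervals(tss_m, span.chrom, max(span.end - 60, span.start),
                           span.end, -v)
        else:
            _add_intervals(tss_p, span.chrom, span.start,
                           min(span.start + 60, span.end), v)
        for bucket in (cons_a, cons_b):
            v = min(rng.uniform(0.05, 0.5) + config.cons_effect * pcg, 1.0)
            frac = rng.uniform(0.4, 1.0)
            _add_intervals(bucket, span.chrom, span.start,
                           span.start + int(frac * n), v)
        for vocab, track in ((remap_vocab, remap), (jaspar_vocab, jaspar)):
            p_hit = min(base_hit + config.remap_effect * pcg, 0.95)
            for reg in vocab:
                if rng.random() < p_hit:
                    s = int(rng.integers(span.start, span.end - 20))
                    track.add(
                        GenomicInterval(span.chrom, s, s + 20, "."), reg
                    )
        p_prom = min(0.3 + config.promoter_effect * pcg, 0.95)
        if rng.random() < p_prom:
            if t.strand == "-":
                epdnew.add(GenomicInterval(span.chrom, span.end + 10,
                                           span.end + 110, "."))
            elif span.start > 120:
                epdnew.add(GenomicInterval(span.chrom, span.start - 110,
                                           span.start - 10, "."))

    return TrackSet(
        tss_plus=_finish_signal("tss_plus", tss_p),
        tss_minus=_finish_signal("tss_minus", tss_m, signed=True),
        pol2=_finish_signal("s2_pol2", pol2),
        h3k4me3=_finish_signal("h3k4me3", h3k),
        cons_a=_finish_signal("pcons27", cons_a),
        cons_b=_finish_signal("phylocons124", cons_b),
        remap=remap,
        tfbs=jaspar,
        epdnew=epdnew,
        chrom_lengths={c: len(s) for c, s in genome.items()},
    )


# ---------------------------------------------------------------------------
# assembled transcriptome with known-truth novel candidates
# ---------------------------------------------------------------------------

def make_assembly(
    genome: dict[str, str],
    reference: Sequence[TranscriptModel],
    config: FixtureConfig,
) -> tuple[list[TranscriptModel], FixtureTruth]:
    """Simulate a merged assembled transcriptome.

    Annotated records mirror the reference with generated MSTRG IDs plus a
    ``ref_gene_id`` link; ``n_novel`` extra transcripts carry generated IDs
    and no reference link, placed geometrically to honour a known subclass
    truth cycling lincRNA -> intronic -> antisense. Per-sample FPKM values
    are attached to every record.
    """
    rng = np.random.default_rng(config.seed + 2)
    samples = [f"sample{i + 1}" for i in range(config.n_samples)]
    truth = FixtureTruth()
    out: list[TranscriptModel] = []

    def fpkm() -> dict[str, float]:
        return {s: float(np.round(rng.lognormal(1.0, 1.0), 3)) for s in samples}

    for i, t in enumerate(reference):
        out.append(
            TranscriptModel(
                transcript_id=f"MSTRG.{i + 1}.1",
                gene_id=f"MSTRG.{i + 1}",
                exons=list(t.exons),
                biotype=t.biotype,
                ref_gene_id=t.gene_id,
                fpkm=fpkm(),
            )
        )

    # geometry helpers for novel placement
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for t in reference:
        by_chrom.setdefault(t.chrom, []).append(t)
    spans = {
        c: sorted((t.span.start, t.span.end) for t in ts)
        for c, ts in by_chrom.items()
    }
    wide_introns = [
        (t, intron)
        for t in reference
        for intron in t.introns()
        if len(intron) >= 400
    ]
    kinds = ["lincRNA", "intronic", "antisense"]
    made = 0
    attempts = 0
    n_ref = len(reference)
    while made < config.n_novel and attempts < config.n_novel * 50:
        attempts += 1
        kind = kinds[made % 3]
        tid = f"MSTRG.{n_ref + made + 1}.1"
        gid = f"MSTRG.{n_ref + made + 1}"
        if kind == "lincRNA":
            chrom = list(genome)[int(rng.integers(len(genome)))]
            length = int(rng.integers(250, 500))
            start = int(rng.integers(100, len(genome[chrom]) - length - 100))
            cand = (start - 1, start + length + 1)
            busy = any(
                cand[0] < e and s < cand[1] for s, e in spans.get(chrom, [])
            )
            if busy:
                continue
            exons = [GenomicInterval(chrom, start, start + length,
                                     "+" if rng.random() < 0.5 else "-")]
        elif kind == "intronic":
            if not wide_introns:
                continue
            host, intron = wide_introns[int(rng.integers(len(wide_introns)))]
            length = min(int(rng.integers(200, 350)), len(intron) - 40)
            start = intron.start + 20
            exons = [GenomicInterval(intron.chrom, start, start + length,
                                     host.strand)]
        else:  # antisense: overlap a reference exon on the opposite strand
            host = reference[int(rng.integers(len(reference)))]
            if host.strand not in ("+", "-"):
                continue
            ex = host.exons[int(rng.integers(len(host.exons)))]
            opp = "-" if host.strand == "+" else "+"
            length = int(rng.integers(250, 450))
            start = max(0, ex.start - length // 3)
            exons = [GenomicInterval(ex.chrom, start, start + length, opp)]
        out.append(
            TranscriptModel(
                transcript_id=tid, gene_id=gid, exons=exons, fpkm=fpkm()
            )
        )
        truth.subclasses[tid] = kind
        made += 1
    if made < config.n_novel:
        raise ValueError("could not place the requested novel transcripts")
    return out, truth


# ---------------------------------------------------------------------------
# direct feature-space simulation
# ---------------------------------------------------------------------------

def make_labeled_dataset(
    n: int = 10_000,
    n_positive: int = 500,
    n_features: int = 20,
    n_informative: int = 3,
    effect: float = 2.0,
    seed: int = 0,
) -> tuple[LabeledDataset, FixtureTruth]:
    """Fast-path labelled matrix: standard-normal noise features plus
    ``n_informative`` features whose positive-class mean is shifted by
    ``effect`` standard deviations. Label counts are exact."""
    if n_positive > n:
        raise ValueError("n_positive cannot exceed n")
    rng = np.random.default_rng(seed)
    y = np.zeros(n, dtype=np.int8)
    y[rng.choice(n, size=n_positive, replace=False)] = 1
    x = rng.standard_normal((n, n_features))
    names = [f"f{i:03d}" for i in range(n_features)]
    planted = names[:n_informative]
    x[y == 1, :n_informative] += effect
    features = pd.DataFrame(x, columns=names,
                            index=[f"row{i}" for i in range(n)])
    truth = FixtureTruth(
        labels={f"row{i}": int(y[i]) for i in range(n)},
        planted_features=planted,
    )
    return LabeledDataset(features, y), truth


# ---------------------------------------------------------------------------
# barcoded reads
# ---------------------------------------------------------------------------

def make_reads(
    config: FixtureConfig, out_dir: str | Path
) -> tuple[list[Path], dict[str, Path], FixtureTruth]:
    """Emit cluster-barcoded FASTQ plus per-cluster barcode whitelists.

    Each read's header carries its cell barcode as a colon-delimited token;
    an ``unassigned_fraction`` of reads gets a barcode outside every
    whitelist. Returns (fastq paths, cluster -> barcode-file path, truth).
    """
    rng = np.random.default_rng(config.seed + 3)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def bc() -> str:
        return "".join(rng.choice(BASES, size=config.barcode_length))

    all_codes: set[str] = set()
    clusters: dict[str, list[str]] = {}
    for c in range(config.n_clusters):
        name = f"cluster{c + 1}"
        codes: list[str] = []
        while len(codes) < config.n_cells_per_cluster:
            b = bc()
            if b not in all_codes:
                all_codes.add(b)
                codes.append(b)
        clusters[name] = codes
    decoys: list[str] = []
    while len(decoys) < max(config.n_cells_per_cluster // 2, 1):
        b = bc()
        if b not in all_codes:
            all_codes.add(b)
            decoys.append(b)

    truth = FixtureTruth(cluster_barcodes=clusters)
    truth.cluster_read_counts = {name: 0 for name in clusters}
    fastq_path = out_dir / "reads_R2.fastq"
    names = list(clusters)
    with open(fastq_path, "w") as fh:
        for i in range(config.n_reads):
            if rng.random() < config.unassigned_fraction:
                code = decoys[int(rng.integers(len(decoys)))]
                cluster = None
            else:
                cluster = names[int(rng.integers(len(names)))]
                codes = clusters[cluster]
                code = codes[int(rng.integers(len(codes)))]
                truth.cluster_read_counts[cluster] += 1
            seq = "".join(rng.choice(BASES, size=config.read_length))
            qual = "I" * config.read_length
            fh.write(f"@SIM:{i:06d}:{code} 2:N:0\n{seq}\n+\n{qual}\n")

    barcode_paths: dict[str, Path] = {}
    for name, codes in clusters.items():
        p = out_dir / f"{name}.barcodes"
        p.write_text("\n".join(codes) + "\n")
        barcode_paths[name] = p
    return [fastq_path], barcode_paths, truth


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_signal_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            starts, ends, values = track.chrom_data(chrom)
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def write_interval_bed(track: IntervalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv, label in zip(track.intervals, track.labels):
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label or '.'}\t0\t{iv.strand}\n"
            )


def write_metadata_csv(samples: Sequence[str], conditions: Sequence[str],
                       path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample", "condition"])
        for s, c in zip(samples, conditions):
            writer.writerow([s, c])


def write_fixture(config: FixtureConfig, out_dir: str | Path) -> dict[str, Path]:
    """Emit a complete on-disk fixture: genome, annotations, tracks, reads.

    Returns a name -> path map of everything written; all files parse with
    the package's own readers.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome, reference, _ = make_reference(config)
    tracks = make_tracks(genome, reference, config)
    assembly, truth = make_assembly(genome, reference, config)

    paths: dict[str, Path] = {}
    paths["genome"] = out_dir / "genome.fa"
    write_fasta(genome, paths["genome"])
    paths["reference_gtf"] = out_dir / "reference.gtf"
    write_annotation(reference, paths["reference_gtf"])
    paths["assembly_gtf"] = out_dir / "assembled.gtf"
    write_annotation(assembly, paths["assembly_gtf"])

    tdir = out_dir / "tracks"
    tdir.mkdir(exist_ok=True)
    for name in ("tss_plus", "tss_minus", "pol2", "h3k4me3", "cons_a", "cons_b"):
        track = getattr(tracks, name)
        paths[name] = tdir / f"{name}.bedgraph"
        write_signal_bedgraph(track, paths[name])
    for name in ("remap", "tfbs", "epdnew"):
        track = getattr(tracks, name)
        paths[name] = tdir / f"{name}.bed"
        write_interval_bed(track, paths[name])

    samples = [f"sample{i + 1}" for i in range(config.n_samples)]
    conditions = ["control" if i % 2 == 0 else "treated" for i in range(len(samples))]
    paths["metadata"] = out_dir / "metadata.csv"
    write_metadata_csv(samples, conditions, paths["metadata"])

    fastqs, barcode_paths, _ = make_reads(config, out_dir / "reads")
    paths["fastq"] = fastqs[0]
    for name, p in barcode_paths.items():
        paths[f"barcodes_{name}"] = p
    # truth tables for downstream audits
    paths["truth_subclasses"] = out_dir / "truth_subclasses.tsv"
    with open(paths["truth_subclasses"], "w") as fh:
        fh.write("transcript_id\tsubclass\n")
        for tid, sub in sorted(truth.subclasses.items()):
            fh.write(f"{tid}\t{sub}\n")
    return paths
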