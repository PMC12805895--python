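"""End-to-end candidate discovery: categorize -> features -> predict -> report.

Consumes a pre-assembled merged transcriptome (alignment and assembly are
upstream of this package), flags novel transcripts, builds the evidence
matrix, scores candidates with a trained — or freshly trained — glass-box
model, and writes one results row per novel candidate with its probability,
coordinates, subclass and per-sample FPKM values. Every run appends stage
progress to ``run.log`` and snapshots the effective configuration.
"""

from __future__ import annotations

import datetime
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import catalog
from .config import RunConfig, parse_metadata
from .features.matrix import FeatureExtractionConfig, TrackSet, assemble_matrix
from .features.schema import build_schema
from .features.sequence import fit_kmer_projector
from .features.tracks import read_bed, read_bedgraph
from .model import (
    HyperParams,
    LabeledDataset,
    ModelBundle,
    classify,
    predict_proba,
    train,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        path.parent.mkdir(parents=True, exist_ok=True)
        self.fh = open(path, "a")

    def write(self, message: str) -> None:
        stamp = datetime.datetime.now().isoformat(timespec="seconds")
        self.fh.write(f"[{stamp}] {message}\n")
        self.fh.flush()
        logger.info(message)

    def close(self) -> None:
        self.fh.close()


def _load_genome(path: Path):
    from pyfaidx import Fasta

    return Fasta(str(path), sequence_always_upper=False)


def _load_tracks(config: RunConfig) -> TrackSet:
    def sig(key: str, negate: bool = False):
        p = config.tracks.get(key)
        if p is None:
            return None
        return read_bedgraph(p, name=key, negate=negate)

    def bed(key: str):
        p = config.tracks.get(key)
        if p is None:
            return None
        return read_bed(p, name=key)

    return TrackSet(
        tss_plus=sig("tss_plus"),
        tss_minus=sig("tss_minus"),
        pol2=sig("pol2"),
        h3k4me3=sig("h3k4me3"),
        cons_a=sig("cons_a"),
        cons_b=sig("cons_b"),
        remap=bed("remap"),
        tfbs=bed("tfbs"),
        epdnew=bed("epdnew"),
    )


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the results_file.csv path.

    Stage failures raise :class:`PipelineError` naming the stage (the CLI
    maps this to a non-zero exit); partial outputs are retained.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = _RunLog(out_dir / "run.log")
    (out_dir / "effective_config.yaml").write_text(config.to_yaml())
    try:
        return _run(config, out_dir, log)
    finally:
        log.close()


def _run(config: RunConfig, out_dir: Path, log: _RunLog) -> Path:
    # -- categorize --------------------------------------------------------
    stage = "categorize"
    log.write(f"stage {stage}: parsing annotations")
    try:
        reference = catalog.parse_annotation(config.reference_gtf, "reference")
        assembled = catalog.parse_annotation(config.assembled_gtf, "assembled")
        novel, _annotated = catalog.flag_novel(assembled, config.generated_prefix)
        subclasses = {
            t.transcript_id: catalog.subclass_noncoding(t, reference).value
            for t in novel
        }
        log.write(
            f"stage {stage}: {len(assembled)} assembled transcripts, "
            f"{len(novel)} novel"
        )
        catalog.write_annotation(novel, out_dir / "novel_candidates.gtf")
        with open(out_dir / "subclasses.tsv", "w") as fh:
            fh.write("transcript_id\tsubclass\n")
            for tid, sub in sorted(subclasses.items()):
                fh.write(f"{tid}\t{sub}\n")
    except Exception as exc:
        log.write(f"stage {stage}: FAILED: {exc}")
        raise PipelineError(stage, str(exc)) from exc

    # -- features ----------------------------------------------------------
    stage = "features"
    log.write(f"stage {stage}: building evidence matrix")
    try:
        genome = _load_genome(config.genome_fasta)
        tracks = _load_tracks(config)
        tracks.chrom_lengths = {name: len(genome[name]) for name in genome.keys()}
        v_remap = sorted(
            {l for l in tracks.remap.labels if l} if tracks.remap else set()
        )
        v_jaspar = sorted(
            {l for l in tracks.tfbs.labels if l} if tracks.tfbs else set()
        )
        k_range = range(config.k_min, config.k_max + 1)
        schema = build_schema(v_remap, v_jaspar, k_range)
        training = catalog.exclude_small_rna(reference)
        labels = np.array(catalog.assign_labels(training))
        corpus = [catalog.extract_sequence(t, genome) for t in training]
        projector = fit_kmer_projector(corpus, k_range, corpus_id="reference")
        fx_cfg = FeatureExtractionConfig(
            upstream_window_bp=config.upstream_window_bp,
            mfe_window_nt=config.mfe_window_nt,
        )
        candidate_matrix = assemble_matrix(
            novel, tracks, genome, projector, schema, fx_cfg
        )
        candidate_matrix.to_csv(out_dir / "features.tsv", sep="\t")
        log.write(
            f"stage {stage}: {candidate_matrix.shape[0]} candidates x "
            f"{candidate_matrix.shape[1]} features"
        )
    except Exception as exc:
        log.write(f"stage {stage}: FAILED: {exc}")
        raise PipelineError(stage, str(exc)) from exc

    # -- predict -----------------------------------------------------------
    stage = "predict"
    try:
        if config.model is not None:
            log.write(f"stage {stage}: loading model {config.model}")
            bundle = ModelBundle.load(config.model)
        else:
            log.write(
                f"stage {stage}: training on the reference annotation "
                f"({len(training)} transcripts)"
            )
            train_matrix = assemble_matrix(
                training, tracks, genome, projector, schema, fx_cfg
            )
            hp = HyperParams(
                learning_rate=0.1, max_rounds=150, seed=config.seed
            )
            bundle = train(
                LabeledDataset(train_matrix, labels), hp,
                schema=schema, projector=projector,
            )
            bundle.save(out_dir / "model.json")
        probabilities = predict_proba(bundle, candidate_matrix)
        calls = classify(probabilities, config.threshold)
        log.write(
            f"stage {stage}: {int(calls.sum())} of {len(calls)} candidates "
            f"called lncRNA at threshold {config.threshold}"
        )
    except Exception as exc:
        log.write(f"stage {stage}: FAILED: {exc}")
        raise PipelineError(stage, str(exc)) from exc

    # -- report ------------------------------------------------------------
    stage = "report"
    try:
        conditions = (
            parse_metadata(config.metadata_csv)
            if config.metadata_csv is not None
            else {}
        )
        samples = sorted({s for t in novel for s in t.fpkm})
        unknown = [s for s in conditions if s not in samples]
        for s in unknown:
            log.write(
                f"stage {stage}: warning: metadata sample {s!r} absent from "
                "expression data"
            )
        rows = []
        for t, p, call in zip(novel, probabilities, calls):
            span = t.span
            row = {
                "id": t.transcript_id,
                "probability": float(p),
                "lncRNA_call": int(call),
                "chrom": span.chrom,
                "start": span.start,
                "end": span.end,
                "strand": t.strand,
                "subclass": subclasses[t.transcript_id],
            }
            for s in samples:
                col = f"FPKM_{s}"
                if s in conditions:
                    col += f"_{conditions[s]}"
                row[col] = t.fpkm.get(s, float("nan"))
            rows.append(row)
        results = pd.DataFrame(rows)
        results_path = out_dir / "results_file.csv"
        results.to_csv(results_path, index=False)
        log.write(f"stage {stage}: wrote {results_path}")
        return results_path
    except PipelineError:
        raise
    except Exception as exc:
        log.write(f"stage {stage}: FAILED: {exc}")
        raise PipelineError(stage, str(exc)) from exc
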