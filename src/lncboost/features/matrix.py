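"""Assembly of the per-candidate evidence matrix.

Track-derived features (signal statistics, overlap fractions, Boolean
regulator fingerprints) are computed over each candidate's genomic span —
the gene's two coordinates — while sequence features (GC content, k-mer
projections, structure MFE, length) are computed over the spliced transcript
sequence. Missing track data imputes 0, so the classifier never sees missing
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from ..catalog import TranscriptModel, extract_sequence
from ..intervals import GenomicInterval, upstream_window
from .schema import FeatureSchema
from .sequence import KmerProjector, gc_content, mfe, project_kmers
from .tracks import (
    IntervalTrack,
    SignalTrack,
    ZERO_STATS,
    boolean_overlap,
    overlap_fraction,
    signal_stats,
)


class ConfigurationError(ValueError):
    pass


@dataclass
class TrackSet:
    """The configured evidence tracks backing the quantitative schema block.

    Any track may be None; its features impute 0. ``tss_minus`` is expected
    signed-negative (minus-strand signal), which is why the schema takes its
    minimum rather than its maximum.
    """

    tss_plus: SignalTrack | None = None
    tss_minus: SignalTrack | None = None
    pol2: SignalTrack | None = None
    h3k4me3: SignalTrack | None = None
    cons_a: SignalTrack | None = None   # PhastCons-style conservation
    cons_b: SignalTrack | None = None   # PhyloP-style conservation
    remap: IntervalTrack | None = None
    tfbs: IntervalTrack | None = None
    epdnew: IntervalTrack | None = None
    chrom_lengths: dict[str, int] = field(default_factory=dict)


@dataclass
class FeatureExtractionConfig:
    upstream_window_bp: int = 500
    #: the Nussinov DP is cubic; fold at most this many 5' bases per transcript
    mfe_window_nt: int = 160
    mfe_engine: Callable[[str], float] | None = None


def _sig(track: SignalTrack | None, span: GenomicInterval) -> dict[str, float]:
    if track is None:
        return dict(ZERO_STATS)
    return signal_stats(track, span)


def _cov(track: IntervalTrack | None, span: GenomicInterval | None) -> float:
    if track is None or span is None:
        return 0.0
    return overlap_fraction(track, span)


def _max_depth(track: IntervalTrack | None, span: GenomicInterval) -> float:
    """Maximum per-base stacking depth of track intervals within the span."""
    if track is None:
        return 0.0
    events: list[tuple[int, int]] = []
    for iv in track.intervals:
        if iv.chrom == span.chrom and iv.start < span.end and iv.end > span.start:
            events.append((max(iv.start, span.start), 1))
            events.append((min(iv.end, span.end), -1))
    if not events:
        return 0.0
    events.sort()
    depth = best = 0
    for _, delta in events:
        depth += delta
        best = max(best, depth)
    return float(best)


def candidate_row(
    t: TranscriptModel,
    tracks: TrackSet,
    genome: Mapping[str, str],
    projector: KmerProjector,
    schema: FeatureSchema,
    config: FeatureExtractionConfig | None = None,
) -> dict[str, float]:
    """Compute one candidate's full feature row as a name -> value mapping."""
    cfg = config or FeatureExtractionConfig()
    span = t.span
    seq = extract_sequence(t, genome)

    row: dict[str, float] = {}
    row["mean_gc"] = gc_content(seq)
    row["cov_tfbs"] = _cov(tracks.tfbs, span)
    row["max_tfbs"] = _max_depth(tracks.tfbs, span)
    row["cov_remap"] = _cov(tracks.remap, span)

    tss_p = _sig(tracks.tss_plus, span)
    row["cov_tss_plus"] = tss_p["cov"]
    row["max_tss_plus"] = tss_p["max"]
    row["sum_tss_plus"] = tss_p["sum"]
    tss_m = _sig(tracks.tss_minus, span)
    row["cov_tss_minus"] = tss_m["cov"]
    row["min_tss_minus"] = tss_m["min"]
    row["sum_tss_minus"] = tss_m["sum"]
    pol2 = _sig(tracks.pol2, span)
    row["cov_s2_pol2"] = pol2["cov"]
    row["sum_s2_pol2"] = pol2["sum"]
    row["max_s2_pol2"] = pol2["max"]
    h3k = _sig(tracks.h3k4me3, span)
    row["cov_h3k4me3"] = h3k["cov"]
    row["mean_h3k4me3"] = h3k["mean"]
    row["sum_h3k4me3"] = h3k["sum"]

    window = upstream_window(
        span, cfg.upstream_window_bp, tracks.chrom_lengths.get(span.chrom)
    )
    row["cov_epdnew"] = _cov(tracks.epdnew, window)

    cons_a = _sig(tracks.cons_a, span)
    row["mean_pcons27"] = cons_a["mean"]
    row["std_pcons27"] = cons_a["std"]
    row["sum_pcons27"] = cons_a["sum"]
    cons_b = _sig(tracks.cons_b, span)
    row["mean_phylocons124"] = cons_b["mean"]
    row["std_phylocons124"] = cons_b["std"]
    row["sum_phylocons124"] = cons_b["sum"]

    if tracks.remap is not None:
        bits = boolean_overlap(tracks.remap, span, schema.v_remap)
    else:
        bits = np.zeros(len(schema.v_remap), dtype=np.int8)
    for name, bit in zip(schema.v_remap, bits):
        row[f"remap_{name}"] = float(bit)
    if tracks.tfbs is not None:
        bits = boolean_overlap(tracks.tfbs, span, schema.v_jaspar)
    else:
        bits = np.zeros(len(schema.v_jaspar), dtype=np.int8)
    for name, bit in zip(schema.v_jaspar, bits):
        row[f"tfbs_{name}"] = float(bit)

    for k, value in project_kmers(projector, seq).items():
        row[f"{k}mer_SVD1"] = value

    fold_seq = seq[: cfg.mfe_window_nt] if cfg.mfe_window_nt else seq
    row["ss_mfe"] = mfe(fold_seq, engine=cfg.mfe_engine)
    row["length"] = float(t.spliced_length)
    return row


def assemble_matrix(
    candidates: Sequence[TranscriptModel],
    tracks: TrackSet,
    genome: Mapping[str, str],
    projector: KmerProjector,
    schema: FeatureSchema,
    config: FeatureExtractionConfig | None = None,
) -> pd.DataFrame:
    """One row per candidate, columns exactly in schema order, no missing values."""
    if tuple(projector.k_range) != tuple(schema.k_range):
        raise ConfigurationError(
            f"projector k_range {projector.k_range} != schema k_range {schema.k_range}"
        )
    rows = []
    index = []
    for t in candidates:
        row = candidate_row(t, tracks, genome, projector, schema, config)
        rows.append([row[c] for c in schema.columns])
        index.append(t.transcript_id)
    df = pd.DataFrame(rows, index=index, columns=list(schema.columns), dtype=float)
    return df.fillna(0.0)
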