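"""Run configuration (YAML) and sample metadata (CSV) parsing."""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

logger = logging.getLogger(__name__)

TRACK_KEYS = (
    "tss_plus", "tss_minus", "pol2", "h3k4me3",
    "cons_a", "cons_b", "remap", "tfbs", "epdnew",
)

_TOP_KEYS = {
    "assembled_gtf", "reference_gtf", "genome_fasta", "tracks", "metadata_csv",
    "out_dir", "threads", "seed", "threshold", "model", "k_min", "k_max",
    "upstream_window_bp", "mfe_window_nt", "generated_prefix",
}
_MANDATORY = ("assembled_gtf", "reference_gtf", "genome_fasta", "out_dir")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    assembled_gtf: Path
    reference_gtf: Path
    genome_fasta: Path
    out_dir: Path
    tracks: dict[str, Path] = field(default_factory=dict)
    metadata_csv: Path | None = None
    model: Path | None = None
    threads: int = 1
    seed: int = 0
    threshold: float = 0.5
    k_min: int = 3
    k_max: int = 12
    upstream_window_bp: int = 500
    mfe_window_nt: int = 160
    generated_prefix: str = "MSTRG."

    def to_yaml(self) -> str:
        doc = {
            "assembled_gtf": str(self.assembled_gtf),
            "reference_gtf": str(self.reference_gtf),
            "genome_fasta": str(self.genome_fasta),
            "out_dir": str(self.out_dir),
            "tracks": {k: str(v) for k, v in self.tracks.items()},
            "threads": self.threads,
            "seed": self.seed,
            "threshold": self.threshold,
            "k_min": self.k_min,
            "k_max": self.k_max,
            "upstream_window_bp": self.upstream_window_bp,
            "mfe_window_nt": self.mfe_window_nt,
            "generated_prefix": self.generated_prefix,
        }
        if self.metadata_csv is not None:
            doc["metadata_csv"] = str(self.metadata_csv)
        if self.model is not None:
            doc["model"] = str(self.model)
        return yaml.safe_dump(doc, sort_keys=True)


def _build_config(doc: dict, base: Path) -> RunConfig:
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    missing = [k for k in _MANDATORY if k not in doc]
    if missing:
        raise ConfigError(f"missing mandatory config key(s): {missing}")

    def path_of(value: str) -> Path:
        p = Path(value)
        return p if p.is_absolute() else base / p

    tracks_doc = doc.get("tracks") or {}
    bad = set(tracks_doc) - set(TRACK_KEYS)
    if bad:
        raise ConfigError(f"unknown track key(s): {sorted(bad)}")
    tracks = {k: path_of(v) for k, v in tracks_doc.items()}

    cfg = RunConfig(
        assembled_gtf=path_of(doc["assembled_gtf"]),
        reference_gtf=path_of(doc["reference_gtf"]),
        genome_fasta=path_of(doc["genome_fasta"]),
        out_dir=path_of(doc["out_dir"]),
        tracks=tracks,
        metadata_csv=path_of(doc["metadata_csv"]) if "metadata_csv" in doc else None,
        model=path_of(doc["model"]) if "model" in doc else None,
        threads=int(doc.get("threads", 1)),
        seed=int(doc.get("seed", 0)),
        threshold=float(doc.get("threshold", 0.5)),
        k_min=int(doc.get("k_min", 3)),
        k_max=int(doc.get("k_max", 12)),
        upstream_window_bp=int(doc.get("upstream_window_bp", 500)),
        mfe_window_nt=int(doc.get("mfe_window_nt", 160)),
        generated_prefix=str(doc.get("generated_prefix", "MSTRG.")),
    )
    if cfg.threads < 1:
        raise ConfigError("threads must be positive")
    if not (0.0 <= cfg.threshold <= 1.0):
        raise ConfigError("threshold must lie in [0, 1]")
    for key in ("assembled_gtf", "reference_gtf", "genome_fasta"):
        p = getattr(cfg, key)
        if not p.exists():
            raise ConfigError(f"{key}: path does not exist: {p}")
    for name, p in cfg.tracks.items():
        if not p.exists():
            raise ConfigError(f"track {name}: path does not exist: {p}")
    if cfg.metadata_csv is not None and not cfg.metadata_csv.exists():
        raise ConfigError(f"metadata_csv: path does not exist: {cfg.metadata_csv}")
    if cfg.model is not None and not cfg.model.exists():
        raise ConfigError(f"model: path does not exist: {cfg.model}")
    return cfg


def parse_config(yaml_path: str | Path) -> RunConfig:
    """Read and validate a YAML run configuration.

    Relative paths resolve against the YAML file's directory. Unknown keys
    are rejected by name; missing mandatory keys and nonexistent paths are
    errors.
    """
    yaml_path = Path(yaml_path)
    doc = yaml.safe_load(yaml_path.read_text())
    if not isinstance(doc, dict):
        raise ConfigError(f"{yaml_path}: config must be a YAML mapping")
    return _build_config(doc, yaml_path.parent)


def parse_metadata(csv_path: str | Path) -> dict[str, str]:
    """Read the sample -> condition map from a two-column CSV with header."""
    csv_path = Path(csv_path)
    out: dict[str, str] = {}
    with open(csv_path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ConfigError(f"{csv_path}: empty metadata file") from None
        if len(header) < 2:
            raise ConfigError(f"{csv_path}: expected columns sample,condition")
        for row in reader:
            if not row or not row[0].strip():
                continue
            sample, condition = row[0].strip(), row[1].strip()
            if sample in out:
                raise ConfigError(f"{csv_path}: duplicate sample {sample!r}")
            out[sample] = condition
    if not out:
        raise ConfigError(f"{csv_path}: no samples in metadata")
    return out
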