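"""Run the complete discovery pipeline on a synthetic fixture.

Emits a fixture to disk (genome, reference and assembled GTFs, evidence
tracks, sample metadata), writes a YAML run config, executes
categorize -> features -> predict -> report, and shows the results file.
"""

import tempfile
from pathlib import Path

import pandas as pd
import yaml

import lncboost as lb
from lncboost.config import parse_config
from lncboost.pipeline import run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    cfg = lb.FixtureConfig(seed=0, n_chromosomes=1, chrom_length=60_000,
                           n_pcg=15, n_ncg=10, n_small_rna=3, n_novel=9)
    paths = lb.write_fixture(cfg, tmp / "fx")

    doc = {
        "assembled_gtf": str(paths["assembly_gtf"]),
        "reference_gtf": str(paths["reference_gtf"]),
        "genome_fasta": str(paths["genome"]),
        "metadata_csv": str(paths["metadata"]),
        "out_dir": str(tmp / "run"),
        "seed": 0,
        "k_min": 3,
        "k_max": 5,
        "tracks": {key: str(paths[key]) for key in
                   ("tss_plus", "tss_minus", "pol2", "h3k4me3", "cons_a",
                    "cons_b", "remap", "tfbs", "epdnew")},
    }
    config_path = tmp / "config.yaml"
    config_path.write_text(yaml.safe_dump(doc))

    results_path = run_pipeline(parse_config(config_path))
    df = pd.read_csv(results_path)
    print(f"results: {len(df)} novel candidates")
    cols = ["id", "probability", "lncRNA_call", "chrom", "start", "end",
            "strand", "subclass"]
    print(df[cols].to_string(index=False))
    # Each row is one novel transcript: its classifier probability of being
    # an lncRNA, the 0/1 call at the configured threshold, genomic span and
    # positional subclass; per-sample FPKM columns (with the metadata
    # condition in the name) follow in the full file.
    print("\nrun log:")
    print((tmp / "run" / "run.log").read_text())
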