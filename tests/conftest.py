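import numpy as np
import pytest

import lncboost as lb
from lncboost import catalog


@pytest.fixture(scope="session")
def tiny_config():
    return lb.FixtureConfig(
        seed=11, n_chromosomes=1, chrom_length=60_000,
        n_pcg=15, n_ncg=10, n_small_rna=3, n_novel=9, n_reads=200,
    )


@pytest.fixture(scope="session")
def genomic_fixture():
    """Full genomic-path fixture: genome, reference, tracks, assembly, truth."""
    cfg = lb.FixtureConfig(seed=5)
    genome, reference, ref_truth = lb.make_reference(cfg)
    tracks = lb.make_tracks(genome, reference, cfg)
    assembly, asm_truth = lb.make_assembly(genome, reference, cfg)
    return {
        "config": cfg,
        "genome": genome,
        "reference": reference,
        "tracks": tracks,
        "assembly": assembly,
        "ref_truth": ref_truth,
        "asm_truth": asm_truth,
    }


@pytest.fixture(scope="session")
def trained_feature_pipeline(genomic_fixture):
    """Schema, projector and training matrix built over the genomic fixture."""
    gf = genomic_fixture
    training = catalog.exclude_small_rna(gf["reference"])
    labels = np.array(catalog.assign_labels(training))
    corpus = [lb.extract_sequence(t, gf["genome"]) for t in training]
    k_range = range(3, 6)
    projector = lb.fit_kmer_projector(corpus, k_range)
    schema = lb.build_schema(
        sorted({l for l in gf["tracks"].remap.labels if l}),
        sorted({l for l in gf["tracks"].tfbs.labels if l}),
        k_range,
    )
    matrix = lb.assemble_matrix(
        training, gf["tracks"], gf["genome"], projector, schema
    )
    return {
        "training": training,
        "labels": labels,
        "projector": projector,
        "schema": schema,
        "matrix": matrix,
    }
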