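"""Schema counting, track statistics, sequence features and matrix assembly."""

import numpy as np
import pytest

import lncboost as lb
from lncboost.features.matrix import ConfigurationError, FeatureExtractionConfig
from lncboost.features.schema import QUANTITATIVE_FEATURES, SchemaError
from lncboost.features.sequence import _first_right_singular_vector, _tfidf_rows
from lncboost.features.tracks import IntervalTrack, SignalTrack
from lncboost.intervals import GenomicInterval, upstream_window


class TestSchema:
    def test_paper_shaped_schema_has_730_columns(self):
        schema = lb.build_schema(
            [f"TF{i:03d}" for i in range(549)],
            [f"MA{i:04d}" for i in range(146)],
            range(3, 13),
        )
        assert len(schema) == 730

    def test_column_count_law(self):
        assert len(lb.build_schema([], [], [3])) == 26
        assert len(lb.build_schema(["a"], ["b", "c"], [3, 4])) == 25 + 1 + 2 + 2

    def test_quantitative_block_has_23_entries(self):
        assert len(QUANTITATIVE_FEATURES) == 23

    def test_duplicate_regulator_rejected(self):
        with pytest.raises(SchemaError, match="dup"):
            lb.build_schema(["dup", "dup"], [], [3])

    def test_deterministic_order(self):
        s1 = lb.build_schema(["b", "a"], ["z", "y"], [4, 3])
        s2 = lb.build_schema(["a", "b"], ["y", "z"], [3, 4])
        assert s1.columns == s2.columns
        assert s1.columns[-2:] == ("ss_mfe", "length")
        assert s1.columns[23:25] == ("remap_a", "remap_b")


def _signal(chrom="chr1", rows=((0, 100, 2.0),), name="s", signed=False):
    t = SignalTrack(name=name, signed=signed)
    starts, ends, values = zip(*rows)
    t.add_chrom(chrom, starts, ends, values)
    return t


def _perbase_oracle(rows, span):
    """Independent per-base expansion of a piecewise-constant signal."""
    vec = np.zeros(span.end - span.start)
    for s, e, v in rows:
        lo, hi = max(s, span.start), min(e, span.end)
        if lo < hi:
            vec[lo - span.start : hi - span.start] = v
    return {
        "cov": float(np.mean(vec != 0)),
        "mean": float(vec.mean()),
        "max": float(vec.max()),
        "min": float(vec.min()),
        "sum": float(vec.sum()),
        "std": float(vec.std()),
    }


class TestSignalStats:
    def test_constant_full_cover(self):
        span = GenomicInterval("chr1", 0, 100)
        stats = lb.signal_stats(_signal(), span)
        assert stats == {"cov": 1.0, "mean": 2.0, "max": 2.0, "min": 2.0,
                         "sum": 200.0, "std": 0.0}

    def test_no_overlap_is_all_zero(self):
        span = GenomicInterval("chr1", 500, 600)
        assert lb.signal_stats(_signal(), span) == {
            "cov": 0.0, "mean": 0.0, "max": 0.0, "min": 0.0, "sum": 0.0,
            "std": 0.0,
        }

    def test_absent_chromosome_zero_with_warning(self, caplog):
        span = GenomicInterval("chrX", 0, 10)
        with caplog.at_level("WARNING"):
            stats = lb.signal_stats(_signal(), span)
        assert stats["sum"] == 0.0
        assert "chrX" in caplog.text

    def test_matches_per_base_oracle_on_random_tracks(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n_iv = int(rng.integers(1, 15))
            pos = 0
            rows = []
            for _ in range(n_iv):
                pos += int(rng.integers(0, 50))
                ln = int(rng.integers(1, 80))
                v = float(np.round(rng.normal(), 3))
                if v != 0:
                    rows.append((pos, pos + ln, v))
                pos += ln
            if not rows:
                continue
            track = _signal(rows=rows)
            s = int(rng.integers(0, pos))
            e = int(rng.integers(s + 1, s + 1000))
            span = GenomicInterval("chr1", s, e)
            got = lb.signal_stats(track, span)
            want = _perbase_oracle(rows, span)
            for key in want:
                assert got[key] == pytest.approx(want[key], abs=1e-9), key


class TestIntervalTrackOps:
    def test_overlap_fraction_examples(self):
        span = GenomicInterval("chr1", 0, 100)
        full = IntervalTrack("t", [GenomicInterval("chr1", 0, 200)])
        assert lb.overlap_fraction(full, span) == 1.0
        two = IntervalTrack("t", [GenomicInterval("chr1", 10, 20),
                                  GenomicInterval("chr1", 50, 60)])
        assert lb.overlap_fraction(two, span) == pytest.approx(0.2)
        away = IntervalTrack("t", [GenomicInterval("chr2", 0, 200)])
        assert lb.overlap_fraction(away, span) == 0.0

    def test_overlapping_intervals_count_union_once(self):
        span = GenomicInterval("chr1", 0, 100)
        t = IntervalTrack("t", [GenomicInterval("chr1", 0, 30),
                                GenomicInterval("chr1", 20, 50)])
        assert lb.overlap_fraction(t, span) == pytest.approx(0.5)

    def test_boolean_overlap_examples(self, caplog):
        span = GenomicInterval("chr1", 100, 200)
        t = IntervalTrack("t")
        t.add(GenomicInterval("chr1", 150, 160), "A")
        t.add(GenomicInterval("chr1", 190, 260), "C")
        t.add(GenomicInterval("chr1", 300, 310), "B")
        t.add(GenomicInterval("chr1", 150, 160), "Z")  # outside vocabulary
        with caplog.at_level("WARNING"):
            vec = lb.boolean_overlap(t, span, ["A", "B", "C"])
        assert vec.tolist() == [1, 0, 1]
        assert "Z" in caplog.text

    def test_boolean_overlap_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(1)
        vocab = [f"R{i}" for i in range(8)]
        t = IntervalTrack("t")
        ivs = []
        for _ in range(120):
            s = int(rng.integers(0, 5000))
            iv = GenomicInterval("chr1", s, s + int(rng.integers(1, 60)))
            label = vocab[int(rng.integers(len(vocab)))]
            t.add(iv, label)
            ivs.append((iv, label))
        for _ in range(200):
            s = int(rng.integers(0, 5000))
            span = GenomicInterval("chr1", s, s + int(rng.integers(1, 300)))
            got = lb.boolean_overlap(t, span, vocab)
            want = [
                int(any(l == r and iv.overlaps(span) for iv, l in ivs))
                for r in vocab
            ]
            assert got.tolist() == want


class TestUpstreamWindow:
    def test_plus_strand(self):
        w = upstream_window(GenomicInterval("c", 1000, 2000, "+"), 500)
        assert (w.start, w.end) == (500, 1000)

    def test_minus_strand(self):
        w = upstream_window(GenomicInterval("c", 1000, 2000, "-"), 500)
        assert (w.start, w.end) == (2000, 2500)

    def test_clipping_at_chromosome_start_and_end(self):
        w = upstream_window(GenomicInterval("c", 100, 200, "+"), 500)
        assert (w.start, w.end) == (0, 100)
        w2 = upstream_window(GenomicInterval("c", 100, 950, "-"), 500,
                             chrom_length=1000)
        assert (w2.start, w2.end) == (950, 1000)


class TestGcContent:
    @pytest.mark.parametrize("seq,expected", [
        ("GGCC", 1.0), ("ATAT", 0.0), ("ACGTN", 0.4), ("acgt", 0.5),
    ])
    def test_examples(self, seq, expected):
        assert lb.gc_content(seq) == pytest.approx(expected)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            lb.gc_content("")


class TestKmerProjector:
    CORPUS = ["ACGTACGTAA", "TTGGCCAACG", "ACACACACAC", "GGGTTTAAAC"]

    def test_identical_corpus_projects_identically(self):
        proj = lb.fit_kmer_projector(["ACGTACGT"] * 5, [3])
        values = {lb.project_kmers(proj, "ACGTACGT")[3] for _ in range(3)}
        assert len(values) == 1

    def test_matches_dense_svd_oracle(self):
        proj = lb.fit_kmer_projector(self.CORPUS, [2])
        vocab, idf, v1 = proj._components[2]
        # independent oracle: explicit binary matrix, sklearn-convention IDF,
        # L2 row norm, dense numpy SVD
        kmers = sorted(vocab, key=vocab.get)
        n = len(self.CORPUS)
        presence = np.array(
            [[1.0 if k in {s[i:i+2] for i in range(len(s) - 1)} else 0.0
              for k in kmers] for s in self.CORPUS]
        )
        df = presence.sum(axis=0)
        idf_oracle = np.log((1 + n) / (1 + df)) + 1
        assert idf == pytest.approx(idf_oracle)
        x = presence * idf_oracle
        x /= np.linalg.norm(x, axis=1, keepdims=True)
        _, _, vt = np.linalg.svd(x)
        assert np.abs(np.dot(vt[0], v1)) == pytest.approx(1.0, abs=1e-9)
        # fitted corpus projections equal the first left-singular component
        got = [lb.project_kmers(proj, s)[2] for s in self.CORPUS]
        assert np.asarray(got) == pytest.approx(x @ v1, abs=1e-9)

    def test_held_out_sequence_matches_explicit_dot_product(self):
        proj = lb.fit_kmer_projector(self.CORPUS, [3])
        vocab, idf, v1 = proj._components[3]
        seq = "ACGTTTGGCA"
        seen = {seq[i:i+3] for i in range(len(seq) - 2)}
        vec = np.zeros(len(vocab))
        for kmer, col in vocab.items():
            if kmer in seen:
                vec[col] = idf[col]
        vec /= np.linalg.norm(vec)
        assert lb.project_kmers(proj, seq)[3] == pytest.approx(
            float(vec @ v1), abs=1e-9
        )

    def test_disjoint_sequence_projects_to_zero(self):
        proj = lb.fit_kmer_projector(["AAAA", "AAAT"], [3])
        assert lb.project_kmers(proj, "GGGGGG")[3] == 0.0

    def test_save_load_round_trip_is_exact(self, tmp_path):
        proj = lb.fit_kmer_projector(self.CORPUS, [2, 3])
        p = tmp_path / "proj.json"
        proj.save(p)
        back = lb.KmerProjector.load(p)
        for s in self.CORPUS + ["ACGTGTCA"]:
            assert lb.project_kmers(back, s) == lb.project_kmers(proj, s)

    def test_sign_convention_largest_loading_positive(self):
        v = _first_right_singular_vector(np.array([[1.0, 3.0], [2.0, 6.0]]))
        assert v[np.argmax(np.abs(v))] > 0


def _mfe_pairs_oracle(seq):
    """Exhaustive enumeration of non-crossing pairings (no memoisation)."""
    pairable = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"),
                ("U", "G")}
    s = seq.upper().replace("T", "U")

    def best(i, j):
        if j - i < 4:
            return 0
        # j unpaired
        out = best(i, j - 1)
        for t in range(i, j - 3):
            if (s[t], s[j]) in pairable:
                out = max(out, 1 + best(i, t - 1) + best(t + 1, j - 1))
        return out

    return best(0, len(s) - 1) if len(s) >= 5 else 0


class TestMfe:
    def test_unpairable_sequence_scores_zero(self):
        assert lb.mfe("AAAAAAA") == 0.0
        assert lb.mfe("") == 0.0

    def test_nested_gc_hairpin(self):
        assert lb.mfe("GGGAAAACCC") == -3.0

    def test_loop_constraint_blocks_short_hairpins(self):
        assert lb.mfe("GAAC") == 0.0   # only 2 unpaired bases possible
        assert lb.mfe("GAAAC") == -1.0

    def test_dp_equals_exhaustive_enumeration(self):
        rng = np.random.default_rng(2)
        bases = np.array(list("ACGU"))
        for _ in range(250):
            n = int(rng.integers(5, 13))
            seq = "".join(rng.choice(bases, size=n))
            assert lb.mfe(seq) == -float(_mfe_pairs_oracle(seq)), seq

    def test_plugin_engine_hook(self):
        assert lb.mfe("GGGAAAACCC", engine=lambda s: -7.5) == -7.5
        # engines returning positive energies are clamped to the 0 ceiling
        assert lb.mfe("AAAA", engine=lambda s: 1.0) == 0.0


class TestAssembleMatrix:
    def test_row_equals_feature_by_feature_recomputation(
        self, genomic_fixture, trained_feature_pipeline
    ):
        from lncboost.features.matrix import candidate_row

        gf, tp = genomic_fixture, trained_feature_pipeline
        t = tp["training"][7]
        row = candidate_row(t, gf["tracks"], gf["genome"], tp["projector"],
                            tp["schema"])
        matrix_row = tp["matrix"].loc[t.transcript_id]
        # spot-check against the individual operators
        seq = lb.extract_sequence(t, gf["genome"])
        assert row["mean_gc"] == lb.gc_content(seq)
        assert row["length"] == t.spliced_length
        pol2 = lb.signal_stats(gf["tracks"].pol2, t.span)
        assert row["cov_s2_pol2"] == pol2["cov"]
        assert row["sum_s2_pol2"] == pol2["sum"]
        assert row["cov_remap"] == lb.overlap_fraction(gf["tracks"].remap, t.span)
        for name in tp["schema"].columns:
            assert matrix_row[name] == row[name], name

    def test_matrix_shape_and_finiteness(self, trained_feature_pipeline):
        m = trained_feature_pipeline["matrix"]
        assert m.shape[1] == len(trained_feature_pipeline["schema"])
        assert np.isfinite(m.to_numpy()).all()
        assert (m["length"] > 0).all()
        assert m["ss_mfe"].le(0).all()
        for col in ("mean_gc", "cov_s2_pol2", "cov_remap", "cov_epdnew"):
            assert m[col].between(0, 1).all()

    def test_candidate_off_track_chromosome_imputes_zero(
        self, genomic_fixture, trained_feature_pipeline
    ):
        from lncboost.catalog import TranscriptModel

        gf, tp = genomic_fixture, trained_feature_pipeline
        genome = dict(gf["genome"])
        genome["chrZ"] = "ACGT" * 200
        t = TranscriptModel("ghost", "ghost",
                            [GenomicInterval("chrZ", 0, 300, "+")])
        m = lb.assemble_matrix([t], gf["tracks"], genome, tp["projector"],
                               tp["schema"])
        assert m.loc["ghost", "cov_s2_pol2"] == 0.0
        assert m.loc["ghost", "sum_h3k4me3"] == 0.0
        assert m.loc["ghost", "mean_gc"] > 0  # sequence features still computed
        assert m.loc["ghost", "length"] == 300.0

    def test_projector_schema_mismatch_raises_before_compute(
        self, genomic_fixture, trained_feature_pipeline
    ):
        gf, tp = genomic_fixture, trained_feature_pipeline
        bad_schema = lb.build_schema([], [], [3])
        with pytest.raises(ConfigurationError):
            lb.assemble_matrix([], gf["tracks"], gf["genome"],
                               tp["projector"], bad_schema)

    def test_assembly_is_deterministic(
        self, genomic_fixture, trained_feature_pipeline
    ):
        gf, tp = genomic_fixture, trained_feature_pipeline
        sub = tp["training"][:10]
        m1 = lb.assemble_matrix(sub, gf["tracks"], gf["genome"],
                                tp["projector"], tp["schema"])
        m2 = lb.assemble_matrix(sub, gf["tracks"], gf["genome"],
                                tp["projector"], tp["schema"])
        assert m1.equals(m2)
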