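"""Sequence-level features: GC content, k-mer TF-IDF/SVD embedding, MFE.

The k-mer embedding reproduces a bag-of-k-mers pipeline: binary k-mer
presence per transcript, TF-IDF weighting fitted on a training corpus, and
the first right-singular vector of the weighted matrix as a 1-D projection —
one value per k. The projector is fitted once on the training corpus and
frozen, so inference always uses the training-time basis.

The built-in minimum-free-energy engine is a unit-energy Nussinov dynamic
program (Watson-Crick + GU pairs, hairpin loops of at least 3 unpaired
bases, -1 per pair). It is a documented structural stand-in with a plug-in
hook (``engine=``) accepting any thermodynamic folder of signature
``str -> float``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from numba import njit
from sklearn.feature_extraction.text import CountVectorizer, TfidfTransformer


def gc_content(seq: str) -> float:
    """(#G + #C) / length; ambiguous bases count in the denominator only."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


# ---------------------------------------------------------------------------
# k-mer TF-IDF + SVD projector
# ---------------------------------------------------------------------------

@dataclass
class KmerProjector:
    """Frozen per-k TF-IDF weights and first right-singular vectors."""

    k_range: tuple[int, ...]
    corpus_id: str = ""
    # per k: (vocabulary: kmer -> column, idf: array, v1: array)
    _components: dict[int, tuple[dict[str, int], np.ndarray, np.ndarray]] = field(
        default_factory=dict, repr=False
    )

    def to_dict(self) -> dict:
        return {
            "format": "lncboost-kmer-projector/1",
            "k_range": list(self.k_range),
            "corpus_id": self.corpus_id,
            "components": {
                str(k): {
                    "vocabulary": sorted(vocab, key=vocab.get),
                    "idf": idf.tolist(),
                    "v1": v1.tolist(),
                }
                for k, (vocab, idf, v1) in self._components.items()
            },
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, payload: dict) -> "KmerProjector":
        if payload.get("format") != "lncboost-kmer-projector/1":
            raise ValueError("not a k-mer projector payload")
        proj = cls(
            k_range=tuple(payload["k_range"]), corpus_id=payload.get("corpus_id", "")
        )
        for k_s, comp in payload["components"].items():
            vocab = {kmer: i for i, kmer in enumerate(comp["vocabulary"])}
            proj._components[int(k_s)] = (
                vocab,
                np.asarray(comp["idf"], dtype=np.float64),
                np.asarray(comp["v1"], dtype=np.float64),
            )
        return proj

    @classmethod
    def load(cls, path: str | Path) -> "KmerProjector":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _first_right_singular_vector(x: np.ndarray) -> np.ndarray:
    """First right-singular vector, sign-fixed (largest-|loading| positive)."""
    # dense SVD: corpora here are modest; determinism matters more than speed
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    v1 = vt[0]
    if v1[np.argmax(np.abs(v1))] < 0:
        v1 = -v1
    return v1


def _tfidf_rows(
    seqs: Sequence[str], k: int, vocab: dict[str, int], idf: np.ndarray
) -> np.ndarray:
    """L2-normalised IDF-weighted binary presence rows (unseen k-mers dropped)."""
    x = np.zeros((len(seqs), len(vocab)), dtype=np.float64)
    for row, seq in enumerate(seqs):
        s = seq.upper()
        seen = {s[i : i + k] for i in range(len(s) - k + 1)}
        for kmer in seen:
            col = vocab.get(kmer)
            if col is not None:
                x[row, col] = idf[col]
        norm = np.linalg.norm(x[row])
        if norm > 0:
            x[row] /= norm
    return x


def fit_kmer_projector(
    corpus: Sequence[str], k_range: Sequence[int], corpus_id: str = ""
) -> KmerProjector:
    """Fit the per-k TF-IDF weighting and SVD basis on a sequence corpus.

    Per k: binary presence matrix over k-mers observed in the corpus, IDF
    weights from document frequencies (smoothed, sklearn convention), L2 row
    normalisation, then the first right-singular vector of the weighted
    matrix. Sequences shorter than k contribute all-zero rows. A corpus of
    identical sequences yields a degenerate but valid projector.
    """
    if not corpus:
        raise ValueError("corpus must be non-empty")
    ks = tuple(sorted(int(k) for k in k_range))
    proj = KmerProjector(k_range=ks, corpus_id=corpus_id)
    upper = [s.upper() for s in corpus]
    for k in ks:
        cv = CountVectorizer(
            analyzer="char", ngram_range=(k, k), binary=True, lowercase=False
        )
        docs = [s if len(s) >= k else "" for s in upper]
        try:
            counts = cv.fit_transform(docs)
        except ValueError:  # empty vocabulary: every sequence shorter than k
            proj._components[k] = ({}, np.zeros(0), np.zeros(0))
            continue
        tfidf = TfidfTransformer()  # smooth IDF + L2 norm
        x = tfidf.fit_transform(counts).toarray()
        vocab = {kmer: int(i) for kmer, i in cv.vocabulary_.items()}
        v1 = _first_right_singular_vector(x)
        proj._components[k] = (vocab, tfidf.idf_.astype(np.float64), v1)
    return proj


def project_kmers(projector: KmerProjector, seq: str) -> dict[int, float]:
    """Project one sequence: one value per k (0 when no corpus k-mer occurs)."""
    out: dict[int, float] = {}
    for k in projector.k_range:
        vocab, idf, v1 = projector._components[k]
        if not vocab:
            out[k] = 0.0
            continue
        row = _tfidf_rows([seq], k, vocab, idf)[0]
        out[k] = float(row @ v1)
    return out


# ---------------------------------------------------------------------------
# RNA secondary-structure MFE (unit-energy Nussinov)
# ---------------------------------------------------------------------------

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}
# allowed pairs: AU, GC, GU (and symmetric)
_PAIRS = {(0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)}

MIN_HAIRPIN = 3  # minimum unpaired bases in a hairpin loop


@njit(cache=True)
def _nussinov_pairs(code: np.ndarray) -> int:  # pragma: no cover - numba
    n = code.shape[0]
    if n < MIN_HAIRPIN + 2:
        return 0
    m = np.zeros((n, n), dtype=np.int32)
    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = m[i + 1, j]
            for t in range(i + MIN_HAIRPIN + 1, j + 1):
                a, b = code[i], code[t]
                paired = (
                    (a == 0 and b == 3) or (a == 3 and b == 0)
                    or (a == 1 and b == 2) or (a == 2 and b == 1)
                    or (a == 2 and b == 3) or (a == 3 and b == 2)
                )
                if paired:
                    inner = m[i + 1, t - 1] if t - 1 >= i + 1 else 0
                    rest = m[t + 1, j] if t + 1 <= j else 0
                    cand = 1 + inner + rest
                    if cand > best:
                        best = cand
            m[i, j] = best
    return int(m[0, n - 1])


def mfe(seq: str, engine: Callable[[str], float] | None = None) -> float:
    """Minimum free energy of the folded sequence (<= 0; 0 when unpairable).

    The default engine scores -1 per base pair found by the Nussinov DP
    (Watson-Crick + GU wobble, hairpin loops >= 3 unpaired bases). Pass
    ``engine`` to delegate to an external thermodynamic folder.
    """
    if engine is not None:
        value = float(engine(seq))
        return min(value, 0.0)
    if not seq:
        return 0.0
    code = np.array(
        [_BASE_CODE.get(c, -1) for c in seq.upper()], dtype=np.int8
    )
    pairs = _nussinov_pairs(code)
    return -float(pairs) if pairs else 0.0
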