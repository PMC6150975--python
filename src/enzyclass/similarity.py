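"""Sequence-similarity scoring and the similarity-vote (kNN) predictor.

The vote score for a query against a class's training set is

    O_B = (S_p - S_n) / (S_p + S_n)

where S_p (S_n) is the summed similarity of the positive (negative) members
among the k most similar training proteins overall.  O_B lies in [-1, +1]
and hits the endpoints exactly when all k neighbours come from one side.
For ensemble combination the score is rescaled to [0, 1] via (O_B + 1) / 2.

The default similarity engine is a Smith-Waterman local aligner (BLOSUM62,
affine gaps: open 11, extend 1, i.e. a gap of length L costs 11 + L) with
scores floored at 0; it is a numba-compiled kernel whose scores are identical
to Bio.Align.PairwiseAligner in local mode.  The engine is a pluggable
contract (`SimilarityBackend`): any callable returning a non-negative score
monotone in alignment quality may stand in, e.g. an adapter over tabular
output of an external search tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .records import ProteinRecord

__all__ = [
    "ALPHABET",
    "blosum62_matrix",
    "encode_sequence",
    "smith_waterman_score",
    "SimilarityBackend",
    "SmithWatermanBackend",
    "TabularHitsBackend",
    "KnnScorer",
    "knn_score",
]

#: 20 canonical residues + X (ambiguous), the encoding alphabet for alignment.
ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_INDEX = {ch: i for i, ch in enumerate(ALPHABET)}

GAP_OPEN = 11
GAP_EXTEND = 1

_NEG_INF = -(10**6)


def blosum62_matrix() -> np.ndarray:
    """BLOSUM62 as a 21x21 int32 array over :data:`ALPHABET` (NCBI values)."""
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    mat = np.zeros((len(ALPHABET), len(ALPHABET)), dtype=np.int32)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            mat[i, j] = blosum[a][b]
    return mat


_B62 = blosum62_matrix()


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode an amino-acid string as int8 indices into :data:`ALPHABET`."""
    try:
        return np.array([_INDEX[c] for c in sequence], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - sanitize upstream
        raise ValueError(f"cannot encode residue {exc.args[0]!r}") from exc


@njit(cache=True)
def _sw_kernel(q, t, mat, gap_open, gap_extend, H, E):  # pragma: no cover - jitted
    n = q.shape[0]
    m = t.shape[0]
    for j in range(m + 1):
        H[j] = 0
        E[j] = _NEG_INF
    best = 0
    oe = gap_open + gap_extend
    for i in range(1, n + 1):
        diag = 0
        F = _NEG_INF
        prof = mat[q[i - 1]]
        for j in range(1, m + 1):
            e = E[j] - gap_extend
            h = H[j] - oe
            if h > e:
                e = h
            E[j] = e
            f = F - gap_extend
            h = H[j - 1] - oe
            if h > f:
                f = h
            F = f
            h = diag + prof[t[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            diag = H[j]
            H[j] = h
            if h > best:
                best = h
    return best


@njit(cache=True)
def _sw_many(q, flat, starts, lengths, mat, gap_open, gap_extend):  # pragma: no cover
    out = np.zeros(starts.shape[0], dtype=np.int32)
    maxlen = 0
    for k in range(lengths.shape[0]):
        if lengths[k] > maxlen:
            maxlen = lengths[k]
    H = np.empty(maxlen + 1, dtype=np.int32)
    E = np.empty(maxlen + 1, dtype=np.int32)
    for k in range(starts.shape[0]):
        t = flat[starts[k] : starts[k] + lengths[k]]
        out[k] = _sw_kernel(q, t, mat, gap_open, gap_extend, H, E)
    return out


def smith_waterman_score(query: str, target: str) -> float:
    """Local-alignment score of two sequences (BLOSUM62, affine gaps, >= 0)."""
    if not query or not target:
        raise ValueError("cannot align an empty sequence")
    q = encode_sequence(query)
    t = encode_sequence(target)
    H = np.empty(len(t) + 1, dtype=np.int32)
    E = np.empty(len(t) + 1, dtype=np.int32)
    return float(_sw_kernel(q, t, _B62, np.int32(GAP_OPEN), np.int32(GAP_EXTEND), H, E))


class SimilarityBackend:
    """Contract for pairwise similarity engines.

    Implementations return a non-negative score for (query, target), higher
    meaning more similar, and should be symmetric in practice.
    """

    def pairwise(self, query: str, target: str) -> float:
        raise NotImplementedError

    def against_many(self, query: str, targets: Sequence[str]) -> np.ndarray:
        return np.array([self.pairwise(query, t) for t in targets], dtype=float)


class SmithWatermanBackend(SimilarityBackend):
    """Default internal backend; caches scores symmetrically by sequence pair."""

    def __init__(self, cache: bool = True) -> None:
        self._cache: dict[tuple[str, str], float] | None = {} if cache else None

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def pairwise(self, query: str, target: str) -> float:
        if self._cache is None:
            return smith_waterman_score(query, target)
        key = self._key(query, target)
        score = self._cache.get(key)
        if score is None:
            score = smith_waterman_score(query, target)
            self._cache[key] = score
        return score

    def against_many(self, query: str, targets: Sequence[str]) -> np.ndarray:
        if not targets:
            return np.zeros(0)
        if not query:
            raise ValueError("cannot align an empty sequence")
        out = np.empty(len(targets), dtype=float)
        todo: list[int] = []
        if self._cache is not None:
            for i, t in enumerate(targets):
                hit = self._cache.get(self._key(query, t))
                if hit is None:
                    todo.append(i)
                else:
                    out[i] = hit
        else:
            todo = list(range(len(targets)))
        if todo:
            q = encode_sequence(query)
            encoded = [encode_sequence(targets[i]) for i in todo]
            lengths = np.array([len(e) for e in encoded], dtype=np.int64)
            starts = np.zeros(len(encoded), dtype=np.int64)
            np.cumsum(lengths[:-1], out=starts[1:])
            flat = np.concatenate(encoded)
            scores = _sw_many(
                q, flat, starts, lengths, _B62, np.int32(GAP_OPEN), np.int32(GAP_EXTEND)
            )
            for pos, i in enumerate(todo):
                out[i] = float(scores[pos])
                if self._cache is not None:
                    self._cache[self._key(query, targets[i])] = out[i]
        return out


class TabularHitsBackend(SimilarityBackend):
    """Adapter over precomputed hits of an external search tool.

    ``hits`` maps (query_id, target_id) -> bit-score-like value; missing pairs
    score 0.  Sequences are looked up by id, so this backend must be used with
    :class:`KnnScorer` instances built with ids.
    """

    def __init__(self, hits: dict[tuple[str, str], float]) -> None:
        self.hits = {k: float(v) for k, v in hits.items()}
        for v in self.hits.values():
            if v < 0:
                raise ValueError("similarity scores must be non-negative")

    def pairwise(self, query: str, target: str) -> float:
        return self.hits.get((query, target), self.hits.get((target, query), 0.0))


@dataclass
class SimilarityHit:
    target_id: str
    score: float
    is_positive: bool


# Karlin-Altschul parameters for gapped BLOSUM62 with open 11 / extend 1
KA_LAMBDA = 0.267
KA_K = 0.041
SIGNIFICANCE_E = 1e-3


def significance_threshold(
    query_len: int,
    target_len: int,
    e_value: float = SIGNIFICANCE_E,
    n_targets: int = 1,
) -> float:
    """Minimum raw alignment score significant at the given E-value.

    Uses the Karlin-Altschul statistic S = ln(K n m / E) / lambda with the
    standard gapped-BLOSUM62 parameters.  The E-value is per *search*, as in
    a database search: with N target sequences the per-pair expectation is
    E / N, so the floor grows by ln(N) / lambda.  Hits below the floor are
    what a search tool would not report, so the vote treats them as absent.
    """
    return float(
        np.log(KA_K * query_len * target_len * n_targets / e_value) / KA_LAMBDA
    )


def _top_k_hits(
    scores: np.ndarray, ids: Sequence[str], labels: np.ndarray, k: int
) -> list[SimilarityHit]:
    """The k highest-scoring hits, ties broken by target id (stable order)."""
    order = sorted(range(len(ids)), key=lambda i: (-scores[i], ids[i]))
    return [
        SimilarityHit(ids[i], float(scores[i]), bool(labels[i])) for i in order[:k]
    ]


def knn_score_from_hits(hits: Sequence[SimilarityHit]) -> tuple[float, bool]:
    """(O_B, no_homology_flag) from a pre-selected neighbour list."""
    s_p = sum(h.score for h in hits if h.is_positive)
    s_n = sum(h.score for h in hits if not h.is_positive)
    total = s_p + s_n
    if total == 0:
        return 0.0, True
    return (s_p - s_n) / total, False


def knn_score(
    query: str,
    positive_train: Sequence[str],
    negative_train: Sequence[str],
    k: int = 5,
    backend: SimilarityBackend | None = None,
) -> float:
    """Signed vote score O_B in [-1, +1] for a raw query sequence.

    Neighbours are the k highest-similarity training proteins across the
    positive and negative sets combined.  Returns 0 when no training protein
    aligns at all (no-homology case).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not positive_train and not negative_train:
        raise ValueError("training sets are empty")
    backend = backend or SmithWatermanBackend()
    seqs = list(positive_train) + list(negative_train)
    labels = np.array([True] * len(positive_train) + [False] * len(negative_train))
    scores = backend.against_many(query, seqs)
    ids = [f"t{i}" for i in range(len(seqs))]
    hits = _top_k_hits(scores, ids, labels, k)
    ob, _ = knn_score_from_hits(hits)
    return ob


@dataclass
class KnnScorer:
    """Trained similarity-vote scorer for one EC class.

    Stores the class's training sequences; scoring a query aligns it against
    all of them, drops hits below the significance floor (what a database
    search would not report), takes the k nearest of the rest and emits
    (O_B + 1) / 2 in [0, 1] — except that a query with *no* significant hit
    scores 0 (no evidence of class membership, rather than half-support).
    A training copy of the query is a legal neighbour (no self-exclusion);
    during cross-validation fold separation removes it naturally.
    """

    ids: list[str]
    sequences: list[str]
    labels: np.ndarray  # bool, True = positive
    k: int = 5
    backend: SimilarityBackend = field(default_factory=SmithWatermanBackend)
    min_hit_score: float | str = "auto"  # "auto" = Karlin-Altschul E=1e-3 floor
    name: str = "BLAST-kNN"

    @classmethod
    def fit(
        cls,
        positives: Sequence[ProteinRecord],
        negatives: Sequence[ProteinRecord],
        k: int = 5,
        backend: SimilarityBackend | None = None,
        min_hit_score: float | str = "auto",
    ) -> "KnnScorer":
        ids = [r.id for r in positives] + [r.id for r in negatives]
        seqs = [r.sequence for r in positives] + [r.sequence for r in negatives]
        labels = np.array([True] * len(positives) + [False] * len(negatives))
        return cls(
            ids,
            seqs,
            labels,
            k=k,
            backend=backend or SmithWatermanBackend(),
            min_hit_score=min_hit_score,
        )

    def _significant_hits(self, query: str) -> list[SimilarityHit]:
        tabular = isinstance(self.backend, TabularHitsBackend)
        if tabular:
            scores = np.array(
                [self.backend.pairwise(query, tid) for tid in self.ids]
            )
        else:
            scores = self.backend.against_many(query, self.sequences)
        if self.min_hit_score == "auto":
            if tabular:
                keep = scores > 0
            else:
                n_targets = len(self.sequences)
                floors = np.array(
                    [
                        significance_threshold(len(query), len(t), n_targets=n_targets)
                        for t in self.sequences
                    ]
                )
                keep = scores >= floors
        else:
            keep = scores >= float(self.min_hit_score)
        idx = np.flatnonzero(keep)
        return _top_k_hits(
            scores[idx], [self.ids[i] for i in idx], self.labels[idx], self.k
        )

    def raw_vote(self, query: str) -> float:
        """O_B in [-1, +1]; 0 with no significant hit (no-homology)."""
        ob, _ = knn_score_from_hits(self._significant_hits(query))
        return ob

    def score(self, record: ProteinRecord) -> float:
        """Ensemble-ready score in [0, 1]; 0 in the no-homology case."""
        query = (
            record.id
            if isinstance(self.backend, TabularHitsBackend)
            else record.sequence
        )
        hits = self._significant_hits(query)
        ob, no_homology = knn_score_from_hits(hits)
        return 0.0 if no_homology else (ob + 1.0) / 2.0

    def score_many(self, records: Sequence[ProteinRecord]) -> np.ndarray:
        return np.array([self.score(r) for r in records])
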