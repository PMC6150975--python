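"""Subsequence Profile Map (SPMap) featurization.

SPMap turns a positive training set into a fixed-length feature map:

1. every overlapping length-``l`` window of every positive sequence is
   extracted (windows containing X are skipped);
2. windows are clustered online: a window joins the existing cluster whose
   representative (founding window) gives the highest ungapped positionwise
   BLOSUM62 score, provided that score reaches the threshold ``t``; otherwise
   it founds a new cluster;
3. clusters holding fewer windows than ``discard_fraction`` x (number of
   positive *proteins*) are discarded; each survivor becomes a probabilistic
   profile  PP_c(i, j) = ln((count(i, j) + 0.01) / S_c)  over positions i and
   the 20 residues j (0.01 is a pseudo-count against log(0));
4. a protein's feature c is exp(max over its windows of
   sum_i PP_c(i, window_i)), clipped into (0, 1].

The feature dimensionality equals the number of retained profiles.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .records import AMINO_ACIDS, ProteinRecord
from .similarity import blosum62_matrix

__all__ = [
    "SubsequenceCluster",
    "ProfileMap",
    "extract_subsequences",
    "subsequence_similarity",
    "cluster_subsequences",
    "build_profiles",
    "subsequence_log_prob",
    "featurize",
]

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_B62_20 = blosum62_matrix()[:20, :20]  # canonical block; X never enters windows
PSEUDO_COUNT = 0.01


def _encode20(window: str) -> np.ndarray | None:
    """Window as indices into the 20-letter alphabet; None if any X/other."""
    try:
        return np.array([_AA_INDEX[c] for c in window], dtype=np.int64)
    except KeyError:
        return None


def extract_subsequences(sequence: str, l: int = 5) -> list[str]:
    """All overlapping length-``l`` windows, in order, skipping X-containing ones."""
    if l < 1:
        raise ValueError("subsequence length l must be >= 1")
    out = []
    for i in range(len(sequence) - l + 1):
        window = sequence[i : i + l]
        if _encode20(window) is not None:
            out.append(window)
    return out


def subsequence_similarity(x: str, y: str) -> int:
    """Ungapped positionwise BLOSUM62 score sum of two equal-length windows."""
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    ex, ey = _encode20(x), _encode20(y)
    if ex is None or ey is None:
        raise ValueError("windows must contain canonical residues only")
    return int(_B62_20[ex, ey].sum())


@dataclass
class SubsequenceCluster:
    """One subsequence cluster: founding representative, member count, counts.

    ``counts`` is an l x 20 matrix of residue counts per position; after
    profile construction ``profile`` holds ln((counts + 0.01) / S_c).
    """

    representative: str
    size: int
    counts: np.ndarray
    profile: np.ndarray | None = None

    @property
    def l(self) -> int:
        return len(self.representative)


def cluster_subsequences(
    subsequences: Sequence[str], t: int = 8
) -> list[SubsequenceCluster]:
    """Online single-pass clustering of length-l windows.

    Each window is scored against every existing cluster's representative;
    it joins the best-scoring cluster if that score >= ``t`` (ties broken by
    earliest-created cluster), else founds a new cluster.  Deterministic in
    input order.
    """
    clusters: list[SubsequenceCluster] = []
    if not subsequences:
        return clusters
    l = len(subsequences[0])
    # growing arrays of representative codes for vectorized scoring
    capacity = 256
    reps = np.zeros((capacity, l), dtype=np.int64)
    n_clusters = 0
    for ss in subsequences:
        if len(ss) != l:
            raise ValueError("all subsequences must share one length")
        code = _encode20(ss)
        if code is None:
            raise ValueError(f"non-canonical residue in window {ss!r}")
        best = -1
        if n_clusters:
            scores = _B62_20[reps[:n_clusters], code].sum(axis=1)
            best = int(np.argmax(scores))  # argmax returns first max: earliest cluster
            if scores[best] < t:
                best = -1
        if best >= 0:
            cl = clusters[best]
            cl.size += 1
            cl.counts[np.arange(l), code] += 1
        else:
            counts = np.zeros((l, 20), dtype=np.int64)
            counts[np.arange(l), code] = 1
            clusters.append(SubsequenceCluster(ss, 1, counts))
            if n_clusters == capacity:
                capacity *= 2
                reps = np.resize(reps, (capacity, l))
            reps[n_clusters] = code
            n_clusters += 1
    return clusters


@dataclass
class ProfileMap:
    """The trained SPMap model: retained probabilistic profiles."""

    l: int
    t: int
    clusters: list[SubsequenceCluster]
    discard_fraction: float = 0.10
    #: stacked profiles, shape (n_profiles, l, 20)
    profiles: np.ndarray = field(default_factory=lambda: np.zeros((0, 0, 20)))

    @property
    def n_features(self) -> int:
        return len(self.clusters)

    # -- serialization ----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "l": self.l,
            "t": self.t,
            "discard_fraction": self.discard_fraction,
            "clusters": [
                {
                    "representative": c.representative,
                    "size": c.size,
                    "counts": c.counts.tolist(),
                }
                for c in self.clusters
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ProfileMap":
        payload = json.loads(Path(path).read_text())
        clusters = [
            SubsequenceCluster(
                c["representative"], c["size"], np.array(c["counts"], dtype=np.int64)
            )
            for c in payload["clusters"]
        ]
        pmap = cls(
            l=payload["l"],
            t=payload["t"],
            clusters=clusters,
            discard_fraction=payload["discard_fraction"],
        )
        pmap._finalize_profiles()
        return pmap

    def _finalize_profiles(self) -> None:
        for c in self.clusters:
            c.profile = np.log((c.counts + PSEUDO_COUNT) / c.size)
        if self.clusters:
            self.profiles = np.stack([c.profile for c in self.clusters])
        else:
            self.profiles = np.zeros((0, self.l, 20))


def build_profiles(
    clusters: Iterable[SubsequenceCluster],
    n_positive: int,
    discard_fraction: float = 0.10,
    *,
    l: int | None = None,
    t: int = 8,
) -> ProfileMap:
    """Discard small clusters and convert the rest to probabilistic profiles.

    ``n_positive`` is the number of *proteins* in the positive training set;
    clusters with fewer members than ``discard_fraction * n_positive`` are
    dropped, order otherwise preserved.
    """
    clusters = list(clusters)
    min_size = discard_fraction * n_positive
    retained = [c for c in clusters if c.size >= min_size]
    if not retained:
        raise ValueError(
            "no profiles retained: every subsequence cluster is smaller than "
            f"{min_size:.1f} members; lower discard_fraction or add training data"
        )
    pmap = ProfileMap(
        l=l if l is not None else retained[0].l,
        t=t,
        clusters=retained,
        discard_fraction=discard_fraction,
    )
    pmap._finalize_profiles()
    return pmap


def subsequence_log_prob(ss: str, profile: np.ndarray) -> float:
    """Log-probability of a window under one profile: sum_i PP(i, ss_i)."""
    code = _encode20(ss)
    if code is None:
        raise ValueError("window contains a non-canonical residue")
    if len(ss) != profile.shape[0]:
        raise ValueError("window length does not match profile")
    return float(profile[np.arange(len(ss)), code].sum())


def featurize(protein: ProteinRecord | str, pmap: ProfileMap) -> np.ndarray:
    """SPMap feature vector: per profile, exp(best window log-probability).

    A protein shorter than ``l`` (or with no X-free window) yields the
    all-zero vector, with a warning.
    """
    sequence = protein if isinstance(protein, str) else protein.sequence
    windows = extract_subsequences(sequence, pmap.l)
    if not windows:
        name = protein if isinstance(protein, str) else protein.id
        warnings.warn(
            f"sequence {name!r} has no length-{pmap.l} window; zero feature vector"
        )
        return np.zeros(pmap.n_features)
    codes = np.array([_encode20(w) for w in windows], dtype=np.int64)
    # gather: profiles (C, l, 20), codes (W, l) -> scores (C, W)
    pos = np.arange(pmap.l)
    per_window = pmap.profiles[:, pos, :][:, :, :]  # (C, l, 20)
    scores = per_window[:, pos[None, :], codes[:, :]].sum(axis=2)  # (C, W)
    best = scores.max(axis=1)
    return np.minimum(np.exp(best), 1.0)


def featurize_many(
    proteins: Sequence[ProteinRecord | str], pmap: ProfileMap
) -> np.ndarray:
    return np.vstack([featurize(p, pmap) for p in proteins])


def fit_profile_map(
    positives: Sequence[ProteinRecord],
    l: int = 5,
    t: int = 8,
    discard_fraction: float = 0.10,
) -> ProfileMap:
    """End-to-end map construction from the positive training proteins."""
    windows: list[str] = []
    for rec in positives:
        windows.extend(extract_subsequences(rec.sequence, l))
    clusters = cluster_subsequences(windows, t=t)
    return build_profiles(
        clusters, n_positive=len(positives), discard_fraction=discard_fraction, l=l, t=t
    )
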