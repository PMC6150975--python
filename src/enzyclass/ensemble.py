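"""Per-EC-class ensemble training.

Each trainable EC class gets an independent binary model made of three base
scorers — the subsequence-profile SVM (SPMap), the similarity-vote kNN and
the physicochemical-descriptor SVM (Pepstats) — combined by AUROC-derived
weights:

    W(m) = R_m^4 / sum_m' R_m'^4

where R_m is the 5-fold cross-validated AUROC of base predictor m on the
class's balanced training set.  The class's acceptance threshold (positive
cutoff) maximizes F1 on held-out validation scores; a global negative cutoff
(default 0.3) below which every main class must fall marks non-enzymes.
"""

from __future__ import annotations

import json
import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .datasets import ClassDataset
from .ec import ECNumber, parse_ec
from .pepstats import MinMaxScaler37, fit_scaler, pepstats_features_many
from .records import ProteinRecord
from .similarity import KnnScorer, SimilarityBackend, SmithWatermanBackend
from .spmap import ProfileMap, featurize_many, fit_profile_map

__all__ = [
    "PREDICTOR_NAMES",
    "SvmOnFeaturesScorer",
    "SpmapScorer",
    "PepstatsScorer",
    "ECClassModel",
    "train_binary_classifier",
    "cross_validate_auroc",
    "auroc",
    "combine_weights",
    "weighted_score",
    "select_positive_cutoff",
    "train_class_model",
]

PREDICTOR_NAMES = ("SPMap", "BLAST-kNN", "Pepstats-SVM")


def train_binary_classifier(
    features: np.ndarray, labels: np.ndarray, *, C: float = 1.0,
    gamma: str | float = "scale", seed: int = 42,
):
    """RBF-kernel SVM with logistic (Platt) score calibration.

    The Platt sigmoid is fit on internal stratified cross-validation folds
    and the margin classifier is then refit on the full data, mapping margins
    into [0, 1] via ``predict_proba``.  Raises if only one class is present.
    """
    labels = np.asarray(labels).astype(int)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes are required to train a classifier")
    n_folds = int(min(3, counts.min()))
    svc = SVC(kernel="rbf", C=C, gamma=gamma, random_state=seed)
    X = np.asarray(features, dtype=float)
    if n_folds < 2:
        raise ValueError("need at least 2 samples per class for calibration")
    model = CalibratedClassifierCV(
        svc,
        method="sigmoid",
        cv=StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed),
        ensemble=False,
    )
    model.fit(X, labels)
    return model


class SvmOnFeaturesScorer:
    """A fitted SVC behind a record -> [0, 1] score interface."""

    name: str = "SVM"

    def __init__(self, svc: SVC) -> None:
        self.svc = svc

    def featurize(self, records: Sequence[ProteinRecord]) -> np.ndarray:
        raise NotImplementedError

    def score_many(self, records: Sequence[ProteinRecord]) -> np.ndarray:
        return self.svc.predict_proba(self.featurize(records))[:, 1]

    def score(self, record: ProteinRecord) -> float:
        return float(self.score_many([record])[0])


class SpmapScorer(SvmOnFeaturesScorer):
    """Subsequence-profile featurization followed by the calibrated SVM."""

    name = "SPMap"

    def __init__(self, pmap: ProfileMap, svc: SVC) -> None:
        super().__init__(svc)
        self.pmap = pmap

    def featurize(self, records: Sequence[ProteinRecord]) -> np.ndarray:
        return featurize_many([r.sequence for r in records], self.pmap)


class PepstatsScorer(SvmOnFeaturesScorer):
    """Scaled physicochemical descriptors followed by the calibrated SVM."""

    name = "Pepstats-SVM"

    def __init__(self, scaler: MinMaxScaler37, svc: SVC) -> None:
        super().__init__(svc)
        self.scaler = scaler

    def featurize(self, records: Sequence[ProteinRecord]) -> np.ndarray:
        return self.scaler.transform(
            pepstats_features_many([r.sequence for r in records])
        )


# ---------------------------------------------------------------------------
# cross-validated AUROC and weighting


def auroc(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """AUROC by the rank (Mann-Whitney) formulation, ties credited 0.5."""
    scores_pos = np.asarray(scores_pos, dtype=float)
    scores_neg = np.asarray(scores_neg, dtype=float)
    if len(scores_pos) == 0 or len(scores_neg) == 0:
        raise ValueError("need scores from both classes")
    pooled = np.concatenate([scores_pos, scores_neg])
    ranks = rankdata(pooled)
    n_pos, n_neg = len(scores_pos), len(scores_neg)
    rank_sum = ranks[:n_pos].sum()
    return (rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def cross_validate_auroc(
    positives: Sequence[ProteinRecord],
    negatives: Sequence[ProteinRecord],
    trainer: Callable[[Sequence[ProteinRecord], Sequence[ProteinRecord]], object],
    folds: int = 5,
    seed: int = 42,
    class_name: str = "",
) -> float:
    """Out-of-fold AUROC of a base predictor.

    ``trainer(pos, neg)`` must return a scorer with ``score_many``; folds are
    stratified and deterministic under ``seed``; out-of-fold scores are pooled
    before the single AUROC computation.
    """
    if len(positives) < folds or len(negatives) < folds:
        raise ValueError(
            f"class {class_name or '?'}: need >= {folds} samples per side for "
            f"{folds}-fold cross-validation "
            f"(have {len(positives)} positive / {len(negatives)} negative)"
        )
    records = list(positives) + list(negatives)
    y = np.array([1] * len(positives) + [0] * len(negatives))
    oof = np.empty(len(records))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(np.zeros(len(records)), y):
        pos_in = [records[i] for i in train_idx if y[i] == 1]
        neg_in = [records[i] for i in train_idx if y[i] == 0]
        scorer = trainer(pos_in, neg_in)
        oof[test_idx] = scorer.score_many([records[i] for i in test_idx])
    return auroc(oof[y == 1], oof[y == 0])


def combine_weights(aurocs: Sequence[float]) -> np.ndarray:
    """Fourth-power AUROC weighting, normalized to sum to 1."""
    r = np.asarray(aurocs, dtype=float)
    if np.any((r < 0) | (r > 1)):
        raise ValueError("AUROC values must lie in [0, 1]")
    fourth = r**4
    total = fourth.sum()
    if total == 0:
        raise ValueError("cannot weight predictors whose AUROCs are all zero")
    return fourth / total


def weighted_score(scores: Sequence[float], weights: Sequence[float]) -> float:
    scores = np.asarray(scores, dtype=float)
    weights = np.asarray(weights, dtype=float)
    return float(np.dot(scores, weights))


def select_positive_cutoff(
    val_scores: Sequence[tuple[float, bool]],
    negative_cutoff: float = 0.3,
    grid_step: float = 0.01,
) -> float:
    """F1-maximizing score cutoff over the grid {0.00, 0.01, ..., 1.00}.

    A validation positive scoring strictly above the cutoff is a TP (else FN);
    a negative strictly above is an FP (else TN).  Ties on F1 break toward the
    largest cutoff; the result is clamped strictly above the negative cutoff.
    """
    scores = np.array([s for s, _ in val_scores], dtype=float)
    labels = np.array([bool(lab) for _, lab in val_scores])
    if labels.all() or not labels.any():
        raise ValueError("validation scores must include both classes")
    grid = np.round(np.arange(0.0, 1.0 + 1e-9, grid_step), 10)
    best_f1, best_cut = -1.0, grid[0]
    for cut in grid:
        above = scores > cut
        tp = int(np.sum(above & labels))
        fp = int(np.sum(above & ~labels))
        fn = int(np.sum(~above & labels))
        denom = 2 * tp + fp + fn
        f1 = 2 * tp / denom if denom else 0.0
        if f1 >= best_f1:  # >= keeps the largest tied cutoff
            best_f1, best_cut = f1, cut
    if best_cut >= 1.0 - grid_step / 2 or best_cut == grid[0]:
        warnings.warn(
            f"F1-optimal cutoff at grid extreme ({best_cut:.2f}); "
            "validation scores may be degenerate or inverted"
        )
    if best_cut <= negative_cutoff:
        clamped = grid[grid > negative_cutoff + 1e-12][0]
        warnings.warn(
            f"selected cutoff {best_cut:.2f} <= negative cutoff "
            f"{negative_cutoff:.2f}; clamping to {clamped:.2f}"
        )
        best_cut = clamped
    return float(best_cut)


# ---------------------------------------------------------------------------
# the per-class model


@dataclass
class ECClassModel:
    """Trained binary unit for one EC class: three scorers + weights + cutoffs."""

    ec: ECNumber
    scorers: dict[str, object]  # name -> scorer with score_many
    weights: np.ndarray  # aligned with PREDICTOR_NAMES
    aurocs: np.ndarray
    positive_cutoff: float
    negative_cutoff: float = 0.3
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(float(np.sum(self.weights)) - 1.0) > 1e-9:
            raise ValueError("ensemble weights must sum to 1")
        if self.positive_cutoff <= self.negative_cutoff:
            raise ValueError("positive cutoff must exceed the negative cutoff")

    def component_scores(self, records: Sequence[ProteinRecord]) -> np.ndarray:
        """(n_records, 3) base-predictor scores in PREDICTOR_NAMES order."""
        return np.column_stack(
            [self.scorers[name].score_many(records) for name in PREDICTOR_NAMES]
        )

    def score_many(self, records: Sequence[ProteinRecord]) -> np.ndarray:
        return self.component_scores(records) @ self.weights

    def score(self, record: ProteinRecord) -> float:
        return float(self.score_many([record])[0])

    # -- serialization ----------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "ec": str(self.ec),
            "weights": self.weights.tolist(),
            "aurocs": self.aurocs.tolist(),
            "positive_cutoff": self.positive_cutoff,
            "negative_cutoff": self.negative_cutoff,
            "metadata": self.metadata,
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=1))
        with open(directory / "scorers.pkl", "wb") as fh:
            pickle.dump(self.scorers, fh)

    @classmethod
    def load(cls, directory: str | Path) -> "ECClassModel":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        with open(directory / "scorers.pkl", "rb") as fh:
            scorers = pickle.load(fh)
        return cls(
            ec=parse_ec(meta["ec"]),
            scorers=scorers,
            weights=np.array(meta["weights"]),
            aurocs=np.array(meta["aurocs"]),
            positive_cutoff=meta["positive_cutoff"],
            negative_cutoff=meta["negative_cutoff"],
            metadata=meta.get("metadata", {}),
        )


def train_class_model(
    ec: ECNumber,
    dataset: ClassDataset,
    records_by_id: dict[str, ProteinRecord],
    *,
    l: int = 5,
    t: int = 8,
    discard_fraction: float = 0.10,
    k: int = 5,
    folds: int = 5,
    negative_cutoff: float = 0.3,
    svm_c: float = 1.0,
    svm_gamma: str | float = "scale",
    seed: int = 42,
    backend: SimilarityBackend | None = None,
) -> ECClassModel:
    """Train the full per-class ensemble.

    Orchestrates: SPMap profile construction on training positives and
    featurization of everything; physicochemical featurization + min-max
    scaling; per-predictor 5-fold cross-validated AUROC; final scorers
    refit on the full training data; fourth-power AUROC weights; positive
    cutoff from the F1 sweep on held-out validation weighted scores.
    """
    backend = backend or SmithWatermanBackend()
    pos_train = [records_by_id[i] for i in dataset.positive_train]
    neg_train = [records_by_id[i] for i in dataset.negative_train]
    pos_val = [records_by_id[i] for i in dataset.positive_val]
    neg_val = [records_by_id[i] for i in dataset.negative_val]

    def spmap_trainer(pos, neg):
        pmap = fit_profile_map(pos, l=l, t=t, discard_fraction=discard_fraction)
        X = featurize_many([r.sequence for r in list(pos) + list(neg)], pmap)
        y = np.array([1] * len(pos) + [0] * len(neg))
        svc = train_binary_classifier(X, y, C=svm_c, gamma=svm_gamma, seed=seed)
        return SpmapScorer(pmap, svc)

    def knn_trainer(pos, neg):
        return KnnScorer.fit(pos, neg, k=k, backend=backend)

    def pepstats_trainer(pos, neg):
        X_raw = pepstats_features_many(
            [r.sequence for r in list(pos) + list(neg)]
        )
        scaler = fit_scaler(X_raw)
        X = scaler.transform(X_raw)
        y = np.array([1] * len(pos) + [0] * len(neg))
        svc = train_binary_classifier(X, y, C=svm_c, gamma=svm_gamma, seed=seed)
        return PepstatsScorer(scaler, svc)

    trainers = {
        "SPMap": spmap_trainer,
        "BLAST-kNN": knn_trainer,
        "Pepstats-SVM": pepstats_trainer,
    }
    aurocs = np.array(
        [
            cross_validate_auroc(
                pos_train, neg_train, trainers[name], folds=folds, seed=seed,
                class_name=str(ec),
            )
            for name in PREDICTOR_NAMES
        ]
    )
    weights = combine_weights(aurocs)
    scorers = {name: trainers[name](pos_train, neg_train) for name in PREDICTOR_NAMES}

    component = np.column_stack(
        [scorers[name].score_many(pos_val + neg_val) for name in PREDICTOR_NAMES]
    )
    val_weighted = component @ weights
    val_labels = [True] * len(pos_val) + [False] * len(neg_val)
    positive_cutoff = select_positive_cutoff(
        list(zip(val_weighted, val_labels)), negative_cutoff=negative_cutoff
    )
    return ECClassModel(
        ec=ec,
        scorers=scorers,
        weights=weights,
        aurocs=aurocs,
        positive_cutoff=positive_cutoff,
        negative_cutoff=negative_cutoff,
        metadata={
            "n_positive_train": len(pos_train),
            "n_negative_train": len(neg_train),
            "n_positive_val": len(pos_val),
            "n_negative_val": len(neg_val),
            "negative_composition": dataset.negative_composition,
            "auroc": {n: float(a) for n, a in zip(PREDICTOR_NAMES, aurocs)},
        },
    )
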