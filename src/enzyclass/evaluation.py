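"""Precision/recall/F1 metrics and level-wise scoring of hierarchical predictions.

Level 0 is the enzyme/non-enzyme gate (positive class: enzyme); Levels 1-4
compare the predicted EC truncated to that level against the truth truncated
to the same level.  "No prediction" counts against recall (an FN for the true
class) but never against precision.  Macro metrics are unweighted means of
per-class precision/recall/F1 over the classes present in the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .ec import ECNumber
from .records import PredictionResult

__all__ = ["LevelReport", "precision_recall_f1", "evaluate_levelwise", "report_frame"]


def precision_recall_f1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = their harmonic mean.

    Zero-denominator conventions: with no positive calls and no missed
    positives (TP=FP=FN=0) all three default to 1.0 (nothing to get wrong);
    with TP=0 and any of FP/FN positive the affected metrics are 0.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp == 0 and fp == 0 and fn == 0:
        return 1.0, 1.0, 1.0
    precision = tp / (tp + fp) if (tp + fp) else (0.0 if fn else 1.0)
    recall = tp / (tp + fn) if (tp + fn) else (0.0 if fp else 1.0)
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall)
        else 0.0
    )
    return precision, recall, f1


@dataclass
class LevelReport:
    """Micro confusion counts and metrics for one level, plus macro variants."""

    level: int
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    precision: float = 0.0
    recall: float = 0.0
    f1: float = 0.0
    macro_precision: float = 0.0
    macro_recall: float = 0.0
    macro_f1: float = 0.0
    #: queries with "no prediction" (flagged; excluded from precision)
    n_no_prediction: int = 0
    per_class: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def finalize(self) -> None:
        self.precision, self.recall, self.f1 = precision_recall_f1(
            self.tp, self.fp, self.fn
        )


def _truncation(ec: ECNumber | None, level: int) -> ECNumber | None:
    if ec is None:
        return None
    return ec.truncate(level)


def evaluate_levelwise(
    predictions: list[PredictionResult],
    truth: dict[str, ECNumber | None],
) -> list[LevelReport]:
    """Score predictions at Levels 0-4 against a truth map.

    ``truth`` maps protein id -> deepest true EC (None for non-enzymes);
    every prediction id must be present.  Level L >= 1 counts only queries
    whose truth reaches level L for recall, while any wrong-or-deeper
    enzyme call contributes a false positive.
    """
    missing = [p.protein_id for p in predictions if p.protein_id not in truth]
    if missing:
        raise KeyError(f"predictions without truth entries: {missing[:5]}")

    reports = []
    # Level 0: enzyme vs non-enzyme
    rep0 = LevelReport(level=0)
    for pred in predictions:
        true_ec = truth[pred.protein_id]
        is_true_enzyme = true_ec is not None
        if pred.label == PredictionResult.NO_PREDICTION:
            rep0.n_no_prediction += 1
            if is_true_enzyme:
                rep0.fn += 1  # counted against recall only
            continue
        called_enzyme = pred.is_enzyme_prediction
        if is_true_enzyme and called_enzyme:
            rep0.tp += 1
        elif is_true_enzyme:
            rep0.fn += 1
        elif called_enzyme:
            rep0.fp += 1
        else:
            rep0.tn += 1
    rep0.finalize()
    p, r, f = precision_recall_f1(rep0.tp, rep0.fp, rep0.fn)
    pn, rn, fnn = precision_recall_f1(rep0.tn, rep0.fn, rep0.fp)
    rep0.per_class = {"enzyme": (p, r, f), "non-enzyme": (pn, rn, fnn)}
    rep0.macro_precision = (p + pn) / 2
    rep0.macro_recall = (r + rn) / 2
    rep0.macro_f1 = (f + fnn) / 2
    reports.append(rep0)

    for level in range(1, 5):
        rep = LevelReport(level=level)
        class_counts: dict[str, dict[str, int]] = {}

        def bump(ec: ECNumber, kind: str) -> None:
            cc = class_counts.setdefault(str(ec), {"tp": 0, "fp": 0, "fn": 0})
            cc[kind] += 1

        truth_classes = {
            str(t) for e in truth.values() if e is not None
            for t in [_truncation(e, level)] if t is not None
        }
        for pred in predictions:
            true_ec = _truncation(truth[pred.protein_id], level)
            pred_ec = _truncation(pred.predicted_ec, level)
            if pred.label == PredictionResult.NO_PREDICTION:
                rep.n_no_prediction += 1
                if true_ec is not None:
                    rep.fn += 1
                    bump(true_ec, "fn")
                continue
            if true_ec is None and pred_ec is None:
                rep.tn += 1
            elif true_ec is None:
                rep.fp += 1
                bump(pred_ec, "fp")
            elif pred_ec is None:
                rep.fn += 1
                bump(true_ec, "fn")
            elif true_ec == pred_ec:
                rep.tp += 1
                bump(true_ec, "tp")
            else:
                rep.fp += 1
                rep.fn += 1
                bump(pred_ec, "fp")
                bump(true_ec, "fn")
        rep.finalize()
        per_class = {}
        macro = []
        for name in sorted(truth_classes):
            cc = class_counts.get(name, {"tp": 0, "fp": 0, "fn": 0})
            prf = precision_recall_f1(cc["tp"], cc["fp"], cc["fn"])
            per_class[name] = prf
            macro.append(prf)
        if macro:
            rep.macro_precision = sum(m[0] for m in macro) / len(macro)
            rep.macro_recall = sum(m[1] for m in macro) / len(macro)
            rep.macro_f1 = sum(m[2] for m in macro) / len(macro)
        rep.per_class = per_class
        reports.append(rep)
    return reports


def report_frame(reports: list[LevelReport]) -> pd.DataFrame:
    """Reports as a tidy DataFrame (one row per level), TSV-ready."""
    return pd.DataFrame(
        [
            {
                "level": r.level,
                "TP": r.tp,
                "FP": r.fp,
                "FN": r.fn,
                "TN": r.tn,
                "precision": round(r.precision, 4),
                "recall": round(r.recall, 4),
                "f1": round(r.f1, 4),
                "macro_precision": round(r.macro_precision, 4),
                "macro_recall": round(r.macro_recall, 4),
                "macro_f1": round(r.macro_f1, 4),
                "no_prediction": r.n_no_prediction,
            }
            for r in reports
        ]
    )
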