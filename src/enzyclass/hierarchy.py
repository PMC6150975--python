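"""Top-down prediction over the trained EC class tree.

A query is first scored by every main-class model (Level 0/1 combined):

* at least one weighted score above its class's positive cutoff -> accept the
  best-scoring class and descend into its trained children;
* every main-class score below the global negative cutoff -> "non-enzyme";
* anything in between -> "no prediction".

At Levels 2-4 only the positive cutoffs apply: accept the best
above-cutoff child and keep descending while trained children exist; if no
child clears its cutoff the query keeps the previous level's EC as the final
label.  Exactly one branch is ever explored, so predicted paths are
consistent by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .ec import ECNumber, parse_ec
from .ensemble import ECClassModel
from .records import PredictionResult, ProteinRecord

__all__ = ["ModelTree", "predict_level", "predict"]


@dataclass
class LevelDecision:
    kind: str  # "accept" | "none_above_cutoff" | "below_negative"
    ec: ECNumber | None = None
    score: float = 0.0


def predict_level(
    protein: ProteinRecord,
    candidates: Sequence[ECClassModel],
    *,
    apply_negative_cutoff: bool = False,
) -> LevelDecision:
    """Score one level's candidate models and decide.

    Accepts the maximum-scoring candidate whose weighted score strictly
    exceeds its class-specific positive cutoff (score ties break toward the
    lexicographically smallest EC).  When ``apply_negative_cutoff`` (main
    classes only) and every score falls below every candidate's negative
    cutoff, reports ``below_negative``; otherwise ``none_above_cutoff``.
    """
    if not candidates:
        raise ValueError("no candidate models at this level")
    scored = [(model.score(protein), model) for model in candidates]
    accepted = [(s, m) for s, m in scored if s > m.positive_cutoff]
    if accepted:
        best_score = max(s for s, _ in accepted)
        best = min(m.ec for s, m in accepted if s == best_score)
        return LevelDecision("accept", best, best_score)
    if apply_negative_cutoff and all(s < m.negative_cutoff for s, m in scored):
        return LevelDecision("below_negative")
    return LevelDecision("none_above_cutoff")


@dataclass
class ModelTree:
    """All trained class models plus the child index derived from EC algebra."""

    models: dict[ECNumber, ECClassModel]
    _children: dict[ECNumber | None, list[ECNumber]] = field(
        default_factory=dict, repr=False
    )

    def __post_init__(self) -> None:
        self._children = {}
        for ec in self.models:
            parent = ec.parent()
            if parent is not None and parent not in self.models:
                raise ValueError(
                    f"model for {ec} present but its parent {parent} is not"
                )
            self._children.setdefault(parent, []).append(ec)
        for kids in self._children.values():
            kids.sort()

    @property
    def main_classes(self) -> list[ECNumber]:
        return self._children.get(None, [])

    def children(self, ec: ECNumber) -> list[ECNumber]:
        return self._children.get(ec, [])

    # -- persistence ------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        index = []
        for ec, model in sorted(self.models.items()):
            sub = str(ec).replace(".", "_")
            model.save(directory / sub)
            index.append(sub)
        (directory / "tree.json").write_text(json.dumps({"classes": index}, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "ModelTree":
        directory = Path(directory)
        manifest = directory / "tree.json"
        if not manifest.exists():
            raise FileNotFoundError(f"not a model directory: {directory}")
        index = json.loads(manifest.read_text())["classes"]
        models = {}
        for sub in index:
            model = ECClassModel.load(directory / sub)
            models[model.ec] = model
        return cls(models)


def predict(protein: ProteinRecord, tree: ModelTree) -> PredictionResult:
    """Traverse the tree top-down and label one query."""
    mains = [tree.models[ec] for ec in tree.main_classes]
    decision = predict_level(protein, mains, apply_negative_cutoff=True)
    if decision.kind == "below_negative":
        return PredictionResult(protein.id, PredictionResult.NON_ENZYME)
    if decision.kind == "none_above_cutoff":
        return PredictionResult(protein.id, PredictionResult.NO_PREDICTION)

    current = decision.ec
    confidence = decision.score
    per_level = {1: (current, decision.score)}
    while True:
        child_ecs = tree.children(current)
        if not child_ecs:
            break
        child_models = [tree.models[ec] for ec in child_ecs]
        decision = predict_level(protein, child_models)
        if decision.kind != "accept":
            break  # finalize with the previous level's EC
        current = decision.ec
        confidence = decision.score
        per_level[current.level] = (current, decision.score)
    return PredictionResult(
        protein.id, str(current), confidence=confidence, per_level_scores=per_level
    )


def predict_many(
    proteins: Sequence[ProteinRecord], tree: ModelTree
) -> list[PredictionResult]:
    return [predict(p, tree) for p in proteins]
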