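"""End-to-end orchestration: records -> class datasets -> trained tree -> metrics.

The CLI subcommands are thin wrappers over these functions; tests and the
synthetic benchmark call them directly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .datasets import (
    ClassDataset,
    build_negative_pool,
    propagate_annotations,
    reduce_redundancy,
    sample_balanced_negatives,
    select_nonenzymes,
    select_trainable_classes,
    split_train_validation,
)
from .ec import ECNumber
from .ensemble import train_class_model
from .evaluation import LevelReport, evaluate_levelwise
from .hierarchy import ModelTree, predict_many
from .records import ProteinRecord
from .similarity import SmithWatermanBackend

logger = logging.getLogger("enzyclass")

__all__ = ["build_class_datasets", "train_tree", "run_synthetic_benchmark"]


def build_class_datasets(
    records: list[ProteinRecord], config: RunConfig | None = None
) -> tuple[dict[ECNumber, ClassDataset], dict[str, list[str]]]:
    """Construct balanced per-class datasets from annotated records.

    Returns (datasets by EC, split manifest with 'train'/'val' id lists).
    One redundancy clustering and one 90/10 cluster split are shared by all
    classes, so a protein is on the same side of the split everywhere.
    """
    config = config or RunConfig()
    class_map = propagate_annotations(records)
    trainable = select_trainable_classes(class_map, config.min_class_size)
    nonenzyme_ids = select_nonenzymes(records)
    clustering = reduce_redundancy(records, config.identity_threshold)
    train_ids, val_ids = split_train_validation(
        clustering,
        val_fraction=config.val_fraction,
        seed=config.seed,
        representatives_only=config.representatives_only,
    )
    train_set, val_set = set(train_ids), set(val_ids)
    logger.info(
        "%d records, %d clusters, %d trainable classes, %d reliable non-enzymes",
        len(records), len(clustering.clusters), len(trainable), len(nonenzyme_ids),
    )

    datasets: dict[ECNumber, ClassDataset] = {}
    for idx, ec in enumerate(trainable):
        positives = class_map[ec]
        pos_train = sorted(positives & train_set)
        pos_val = sorted(positives & val_set)
        if len(pos_train) < config.folds or not pos_val:
            warnings.warn(
                f"class {ec}: too few redundancy-reduced members "
                f"(train {len(pos_train)}, val {len(pos_val)}); skipped"
            )
            continue
        pool = build_negative_pool(ec, class_map, nonenzyme_ids)
        pool_train = {k: sorted(set(v) & train_set) for k, v in pool.items()}
        pool_val = {k: sorted(set(v) & val_set) for k, v in pool.items()}
        mix = config.main_mix if ec.level == 1 else config.sublevel_mix
        class_seed = config.seed + 1000 + idx
        neg_train = sample_balanced_negatives(
            pool_train, len(pos_train), mix, seed=class_seed
        )
        neg_val = sample_balanced_negatives(
            pool_val, len(pos_val), mix, seed=class_seed + 1
        )
        composition = _composition(neg_train, pool_train)
        composition.update(
            {f"val_{k}": v for k, v in _composition(neg_val, pool_val).items()}
        )
        datasets[ec] = ClassDataset(
            ec=ec,
            positive_train=pos_train,
            negative_train=neg_train,
            positive_val=pos_val,
            negative_val=neg_val,
            negative_composition=composition,
        )
    manifest = {"train": train_ids, "val": val_ids}
    return datasets, manifest


def _composition(chosen: list[str], pool: dict[str, list[str]]) -> dict[str, int]:
    chosen_set = set(chosen)
    return {key: len(chosen_set & set(ids)) for key, ids in pool.items()}


def train_tree(
    records: list[ProteinRecord],
    datasets: dict[ECNumber, ClassDataset],
    config: RunConfig | None = None,
) -> ModelTree:
    """Train one ensemble model per class dataset and assemble the tree.

    A single cached Smith-Waterman backend is shared by every class's kNN
    scorer, so each distinct sequence pair is aligned at most once per run.
    """
    config = config or RunConfig()
    by_id = {r.id: r for r in records}
    backend = SmithWatermanBackend()
    models = {}
    for ec in sorted(datasets):
        dataset = datasets[ec]
        logger.info(
            "training %s (%d positives)", ec, len(dataset.positive_train)
        )
        model = train_class_model(
            ec,
            dataset,
            by_id,
            l=config.l,
            t=config.t,
            discard_fraction=config.discard_fraction,
            k=config.k,
            folds=config.folds,
            negative_cutoff=config.negative_cutoff,
            svm_c=config.svm_c,
            svm_gamma=config.svm_gamma,
            seed=config.seed,
            backend=backend,
        )
        logger.info(
            "  AUROC %s -> weights %s, positive cutoff %.2f",
            np.round(model.aurocs, 3), np.round(model.weights, 3),
            model.positive_cutoff,
        )
        models[ec] = model
    return ModelTree(models)


@dataclass
class BenchmarkResult:
    """Everything a benchmark run produced, for reporting and audit."""

    tree: ModelTree
    reports: list[LevelReport]
    n_test: int
    manifest: dict[str, list[str]]


def run_synthetic_benchmark(
    seed: int,
    n_main: int = 6,
    members_per_family: int = 80,
    n_nonenzymes: int = 480,
    mutation_rate: float = 0.05,
    length_range: tuple[int, int] = (120, 400),
    config: RunConfig | None = None,
    sublevels: dict[str, list[str]] | None = None,
) -> BenchmarkResult:
    """Generate a toy proteome, train the full tree, score the held-out split.

    The held-out test set is every redundancy-cluster representative the
    90/10 split assigned to validation (enzymes and non-enzymes alike); the
    same validation enzymes drive each class's cutoff sweep, so this mirrors
    a validation-performance analysis.
    """
    from .synthetic import default_hierarchy, generate_benchmark

    config = config or RunConfig(seed=seed, min_class_size=50)
    specs = default_hierarchy(
        n_main=n_main,
        members_per_family=members_per_family,
        mutation_rate=mutation_rate,
        length_range=length_range,
        seed=seed,
        sublevels=sublevels,
    )
    records = generate_benchmark(specs, n_nonenzymes=n_nonenzymes, seed=seed)
    datasets, manifest = build_class_datasets(records, config)
    tree = train_tree(records, datasets, config)

    by_id = {r.id: r for r in records}
    test_records = [by_id[i] for i in manifest["val"]]
    truth = {
        r.id: (next(iter(r.ec_annotations)) if r.ec_annotations else None)
        for r in test_records
    }
    predictions = predict_many(test_records, tree)
    reports = evaluate_levelwise(predictions, truth)
    return BenchmarkResult(
        tree=tree, reports=reports, n_test=len(test_records), manifest=manifest
    )
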