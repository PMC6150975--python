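"""Per-class training/validation dataset construction.

Implements the dataset rules of the hierarchical binary-classifier design:

* EC annotations are propagated to every ancestor class; proteins carrying
  more than one distinct EC number are discarded outright (multi-functional
  enzymes confuse binary classifiers).
* Only classes with at least ``min_count`` member proteins are trainable.
* The negative pool for class e is the union of (i) proteins under e's
  siblings and their descendants, (ii) proteins under other EC main classes,
  and (iii) reliable non-enzymes (annotation score >= 4 and no EC) —
  excluding anything under e itself.  Negative sets are sampled balanced to
  the positive-set size.
* Redundancy is reduced by greedy longest-first identity clustering (>= 50%
  global identity joins a cluster), and train/validation splits assign whole
  clusters to one side so no near-duplicate pair straddles the split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil

import numpy as np

from .ec import ECNumber, ec_relations, sort_ec
from .records import ProteinRecord

__all__ = [
    "ClassDataset",
    "RedundancyClustering",
    "propagate_annotations",
    "select_trainable_classes",
    "select_nonenzymes",
    "build_negative_pool",
    "sample_balanced_negatives",
    "reduce_redundancy",
    "split_train_validation",
    "MAIN_CLASS_MIX",
    "SUBLEVEL_MIX",
]

#: negative-mix fractions (sibling-branch enzymes, other-main enzymes, non-enzymes)
MAIN_CLASS_MIX = (0.0, 0.5, 0.5)
SUBLEVEL_MIX = (0.5, 0.25, 0.25)
POOL_KEYS = ("sibling_branch", "other_main", "nonenzyme")


@dataclass
class ClassDataset:
    """Balanced positive/negative train+validation sets for one EC class."""

    ec: ECNumber
    positive_train: list[str]
    negative_train: list[str]
    positive_val: list[str]
    negative_val: list[str]
    #: counts of negative-set members per origin partition (train, then val)
    negative_composition: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pos = set(self.positive_train) | set(self.positive_val)
        neg = set(self.negative_train) | set(self.negative_val)
        if pos & neg:
            raise ValueError(f"{self.ec}: positive and negative sets overlap")
        if set(self.positive_train) & set(self.positive_val) or set(
            self.negative_train
        ) & set(self.negative_val):
            raise ValueError(f"{self.ec}: train and validation sets overlap")


def propagate_annotations(
    records: list[ProteinRecord],
) -> dict[ECNumber, set[str]]:
    """Map each EC class to the ids annotated with it or any descendant.

    Proteins with more than one distinct EC annotation (before propagation)
    are excluded entirely.
    """
    class_map: dict[ECNumber, set[str]] = {}
    for rec in records:
        if len(rec.ec_annotations) != 1:
            continue  # non-enzymes and multi-EC proteins contribute nothing
        (ec,) = rec.ec_annotations
        for node in [ec, *ec.ancestors()]:
            class_map.setdefault(node, set()).add(rec.id)
    return class_map


def select_trainable_classes(
    class_map: dict[ECNumber, set[str]], min_count: int = 50
) -> list[ECNumber]:
    """Classes with >= min_count members, sorted by level then components."""
    return sort_ec(ec for ec, members in class_map.items() if len(members) >= min_count)


def select_nonenzymes(
    records: list[ProteinRecord], min_annotation_score: int = 4
) -> list[str]:
    """Ids of reliably annotated non-enzymes (no EC, score >= threshold)."""
    return [
        rec.id
        for rec in records
        if not rec.ec_annotations
        and rec.annotation_score is not None
        and rec.annotation_score >= min_annotation_score
    ]


def build_negative_pool(
    ec: ECNumber,
    class_map: dict[ECNumber, set[str]],
    nonenzyme_ids: list[str],
) -> dict[str, list[str]]:
    """Partitioned negative candidate pool for one class.

    ``sibling_branch``: proteins under siblings of ``ec`` (and, through
    propagation, their descendants); ``other_main``: proteins under EC main
    classes other than ec's; ``nonenzyme``: the reliable non-enzymes.  Any
    protein under ``ec`` itself is excluded from every partition, and the
    partitions are mutually disjoint.
    """
    positives = class_map.get(ec, set())
    sibling_branch: set[str] = set()
    other_main: set[str] = set()
    for node, members in class_map.items():
        rel = ec_relations(ec, node)
        if node.main_class != ec.main_class:
            if node.level == 1:
                other_main |= members
            continue
        if rel == "sibling":
            sibling_branch |= members
    sibling_branch -= positives
    other_main -= positives
    other_main -= sibling_branch
    nonenzyme = [pid for pid in nonenzyme_ids if pid not in positives]
    return {
        "sibling_branch": sorted(sibling_branch),
        "other_main": sorted(other_main),
        "nonenzyme": sorted(nonenzyme),
    }


def sample_balanced_negatives(
    pool: dict[str, list[str]],
    n_positive: int,
    mix: tuple[float, float, float] | None = None,
    seed: int = 42,
) -> list[str]:
    """Draw exactly ``n_positive`` negatives without replacement per the mix.

    ``mix`` gives the target fractions over (sibling_branch, other_main,
    nonenzyme) and must sum to 1; the default is the main-class mix (half
    enzymes from other main classes, half non-enzymes).  When a partition is
    exhausted the deficit is refilled from the other partitions with a
    warning.  Deterministic under ``seed``.
    """
    if mix is None:
        mix = MAIN_CLASS_MIX
    if abs(sum(mix) - 1.0) > 1e-9:
        raise ValueError(f"mix fractions must sum to 1, got {mix}")
    total_available = sum(len(pool.get(k, [])) for k in POOL_KEYS)
    if total_available < n_positive:
        raise ValueError(
            f"negative pool ({total_available}) smaller than requested {n_positive}"
        )
    rng = np.random.default_rng(seed)
    # largest-remainder apportionment of n_positive over the mix
    raw = [f * n_positive for f in mix]
    quota = [int(x) for x in raw]
    remainders = sorted(
        range(3), key=lambda i: (raw[i] - quota[i], -i), reverse=True
    )
    for i in remainders[: n_positive - sum(quota)]:
        quota[i] += 1

    chosen: list[str] = []
    deficit = 0
    leftovers: dict[str, list[str]] = {}
    for key, want in zip(POOL_KEYS, quota):
        candidates = list(pool.get(key, []))
        rng.shuffle(candidates)
        take = min(want, len(candidates))
        chosen.extend(candidates[:take])
        leftovers[key] = candidates[take:]
        deficit += want - take
    if deficit:
        warnings.warn(
            f"negative mix partition exhausted; refilling {deficit} draws "
            "from the remaining partitions"
        )
        spare = [pid for key in POOL_KEYS for pid in leftovers[key]]
        chosen.extend(spare[:deficit])
    return chosen


# ---------------------------------------------------------------------------
# redundancy reduction


@dataclass
class RedundancyClustering:
    """Greedy identity clustering: (representative, members) per cluster."""

    clusters: list[tuple[str, list[str]]]
    identity_threshold: float

    @property
    def representatives(self) -> list[str]:
        return [rep for rep, _ in self.clusters]

    def member_ids(self) -> list[str]:
        return [pid for _, members in self.clusters for pid in members]


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment length.

    Computed from the cigar of an end-to-end (Needleman-Wunsch style, unit
    cost) alignment: alignment length = matches + mismatches + indels and
    matches = alignment length - edit distance.
    """
    import edlib

    res = edlib.align(a, b, mode="NW", task="path")
    alen = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            alen += int(num)
            num = ""
    matches = alen - res["editDistance"]
    return matches / alen if alen else 0.0


def _kmer_set(seq: str, k: int = 3) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def reduce_redundancy(
    records: list[ProteinRecord],
    identity_threshold: float = 0.5,
) -> RedundancyClustering:
    """Greedy longest-first clustering at the given global-identity threshold.

    Sequences are processed longest first; each joins the first existing
    cluster whose representative shares >= threshold identity, else founds a
    new cluster.  A k-mer prefilter skips alignments that cannot possibly
    reach the threshold (a global alignment with identity f forces the
    shorter sequence to share at least a commensurate fraction of its 3-mers
    with the representative).
    """
    if not records:
        raise ValueError("no records to cluster")
    if not (0.0 < identity_threshold <= 1.0):
        raise ValueError("identity threshold must be in (0, 1]")
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    reps: list[ProteinRecord] = []
    rep_kmers: list[set[str]] = []
    members: list[list[str]] = []
    k = 3
    for rec in ordered:
        km = _kmer_set(rec.sequence, k)
        assigned = False
        for idx, rep in enumerate(reps):
            # Heuristic prefilter, applied to long sequences only: two
            # sequences sharing >= threshold identity in a global alignment
            # share long identical stretches in practice, hence many 3-mers.
            # Requiring 3-mer coverage of half the needed matches skips the
            # (quadratic) alignments against unrelated sequences.
            if len(rec.sequence) > 80 and len(rep.sequence) > 80:
                need_matches = identity_threshold * max(
                    len(rec.sequence), len(rep.sequence)
                )
                if len(km & rep_kmers[idx]) * k < need_matches * 0.5:
                    continue
            if pairwise_identity(rec.sequence, rep.sequence) >= identity_threshold:
                members[idx].append(rec.id)
                assigned = True
                break
        if not assigned:
            reps.append(rec)
            rep_kmers.append(km)
            members.append([rec.id])
    clusters = [(rep.id, mem) for rep, mem in zip(reps, members)]
    return RedundancyClustering(clusters, identity_threshold)


def split_train_validation(
    clustering: RedundancyClustering,
    val_fraction: float = 0.1,
    seed: int = 42,
    representatives_only: bool = True,
) -> tuple[list[str], list[str]]:
    """Assign whole clusters to train/validation (90/10 by default).

    Validation receives ceil(val_fraction * #clusters) clusters, drawn
    uniformly under ``seed``.  By default only cluster representatives are
    returned; set ``representatives_only=False`` for full memberships.
    """
    n = len(clustering.clusters)
    if n == 0:
        raise ValueError("empty clustering")
    if n == 1:
        warnings.warn("single cluster: everything assigned to training")
        rep, mem = clustering.clusters[0]
        return ([rep] if representatives_only else list(mem)), []
    rng = np.random.default_rng(seed)
    n_val = ceil(val_fraction * n)
    order = rng.permutation(n)
    val_idx = set(order[:n_val].tolist())
    train: list[str] = []
    val: list[str] = []
    for i, (rep, mem) in enumerate(clustering.clusters):
        bucket = val if i in val_idx else train
        bucket.extend([rep] if representatives_only else mem)
    return train, val
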