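"""Synthetic toy proteome generator.

Enzyme families are emulated as random background sequence with short
conserved motifs implanted — the signal all three base predictors can
exploit (subsequence profiles pick up the motif windows, local alignment
scores the shared motifs, and motif residues nudge the composition).  Child
families inherit every ancestor motif plus their own, so EC levels are
separable.  Non-enzymes are motif-free background with a 5-star annotation
score.  Everything is deterministic under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ec import ECNumber, parse_ec
from .io import write_annotation_table, write_fasta
from .records import AMINO_ACIDS, ProteinRecord

__all__ = ["FamilySpec", "generate_family", "generate_benchmark", "default_hierarchy"]

UNIFORM_COMPOSITION = tuple(1.0 / 20 for _ in AMINO_ACIDS)

#: rough Swiss-Prot-like background amino-acid frequencies (A..Y order)
SWISSPROT_COMPOSITION = (
    0.0826, 0.0137, 0.0546, 0.0672, 0.0386, 0.0708, 0.0227, 0.0593, 0.0581,
    0.0965, 0.0241, 0.0406, 0.0472, 0.0393, 0.0553, 0.0660, 0.0535, 0.0687,
    0.0110, 0.0292,
)


@dataclass
class FamilySpec:
    """One motif-defined enzyme family.

    ``motifs`` are (motif string, position policy) pairs; the policy is
    either the string "uniform" (uniform random placement, non-overlapping
    in implant order) or an integer offset.  Each implanted motif residue is
    independently replaced by a random residue with probability
    ``mutation_rate``.
    """

    ec: ECNumber
    motifs: list[tuple[str, str | int]]
    n_members: int = 80
    length_range: tuple[int, int] = (120, 400)
    mutation_rate: float = 0.05
    background: tuple[float, ...] = UNIFORM_COMPOSITION
    id_prefix: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.mutation_rate < 1.0):
            raise ValueError("mutation rate must be in [0, 1)")
        total_motif = sum(len(m) for m, _ in self.motifs)
        if total_motif > self.length_range[0]:
            raise ValueError(
                f"{self.ec}: motifs ({total_motif} residues) do not fit the "
                f"minimum sequence length {self.length_range[0]}"
            )
        if abs(sum(self.background) - 1.0) > 1e-6:
            raise ValueError("background composition must sum to 1")


def _background(rng: np.random.Generator, length: int, comp) -> np.ndarray:
    return rng.choice(20, size=length, p=np.asarray(comp))


def _write_motif(
    seq: np.ndarray, motif: str, start: int, mutation_rate: float,
    rng: np.random.Generator,
) -> None:
    m = len(motif)
    codes = np.array([AMINO_ACIDS.index(c) for c in motif])
    if mutation_rate > 0:
        mutate = rng.random(m) < mutation_rate
        codes = np.where(mutate, rng.integers(0, 20, size=m), codes)
    seq[start : start + m] = codes


def _layout_uniform(
    rng: np.random.Generator,
    length: int,
    motif_lengths: list[int],
    fixed: list[tuple[int, int]],
) -> list[int]:
    """Non-overlapping random starts for the free-position motifs.

    Uses a stars-and-bars layout (random slack distributed between motifs in
    implant order), which always succeeds when the motifs fit the sequence;
    collisions with fixed-offset motifs are resolved by retry.
    """
    total = sum(motif_lengths)
    slack = length - total
    if slack < 0:
        raise ValueError("motifs do not fit the sequence")
    for _ in range(200):
        cuts = np.sort(rng.integers(0, slack + 1, size=len(motif_lengths)))
        starts = []
        consumed = 0
        for gap, m in zip(cuts, motif_lengths):
            starts.append(int(gap) + consumed)
            consumed += m
        if all(
            s + m <= fs or s >= fe
            for s, m in zip(starts, motif_lengths)
            for fs, fe in fixed
        ):
            return starts
    raise ValueError("could not place motifs without overlapping fixed offsets")


def generate_family(spec: FamilySpec, seed: int) -> list[ProteinRecord]:
    """Generate one family's members, annotated with the family EC."""
    rng = np.random.default_rng(seed)
    records = []
    prefix = spec.id_prefix or f"ec{str(spec.ec).replace('.', '_').replace('-', 'x')}"
    for i in range(spec.n_members):
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        seq = _background(rng, length, spec.background)
        fixed: list[tuple[int, int]] = []
        for motif, policy in spec.motifs:
            if isinstance(policy, int):
                if policy < 0 or policy + len(motif) > length:
                    raise ValueError(f"motif offset {policy} out of range")
                fixed.append((policy, policy + len(motif)))
        free_motifs = [m for m, p in spec.motifs if not isinstance(p, int)]
        starts = _layout_uniform(rng, length, [len(m) for m in free_motifs], fixed)
        for (motif, policy) in spec.motifs:
            if isinstance(policy, int):
                _write_motif(seq, motif, policy, spec.mutation_rate, rng)
        for motif, start in zip(free_motifs, starts):
            _write_motif(seq, motif, start, spec.mutation_rate, rng)
        records.append(
            ProteinRecord(
                id=f"{prefix}_{i:04d}",
                sequence="".join(AMINO_ACIDS[c] for c in seq),
                ec_annotations={spec.ec},
                annotation_score=5,
                is_enzyme=True,
            )
        )
    return records


def random_motif(rng: np.random.Generator, length: int = 10) -> str:
    return "".join(AMINO_ACIDS[c] for c in rng.integers(0, 20, size=length))


def default_hierarchy(
    n_main: int = 6,
    members_per_family: int = 80,
    mutation_rate: float = 0.05,
    length_range: tuple[int, int] = (120, 400),
    motifs_per_family: int = 3,
    motif_length: int = 20,
    seed: int = 0,
    sublevels: dict[str, list[str]] | None = None,
    background: tuple[float, ...] = UNIFORM_COMPOSITION,
) -> list[FamilySpec]:
    """Specs for a toy EC tree: ``n_main`` main classes, optional children.

    ``sublevels`` maps a parent EC string to child EC strings; children
    inherit the parent's motifs and add their own ``motifs_per_family``.
    """
    rng = np.random.default_rng(seed)
    specs: list[FamilySpec] = []
    motifs_by_ec: dict[str, list[tuple[str, str | int]]] = {}
    for c in range(1, n_main + 1):
        ec = parse_ec(f"{c}.-.-.-")
        motifs = [
            (random_motif(rng, motif_length), "uniform")
            for _ in range(motifs_per_family)
        ]
        motifs_by_ec[str(ec)] = motifs
        specs.append(
            FamilySpec(
                ec=ec,
                motifs=motifs,
                n_members=members_per_family,
                length_range=length_range,
                mutation_rate=mutation_rate,
                background=background,
            )
        )
    for parent, children in (sublevels or {}).items():
        if parent not in motifs_by_ec:
            raise ValueError(f"unknown parent {parent} in sublevels")
        for child in children:
            own = [
                (random_motif(rng, motif_length), "uniform")
                for _ in range(motifs_per_family)
            ]
            motifs_by_ec[child] = motifs_by_ec[parent] + own
            specs.append(
                FamilySpec(
                    ec=parse_ec(child),
                    motifs=motifs_by_ec[child],
                    n_members=members_per_family,
                    length_range=length_range,
                    mutation_rate=mutation_rate,
                    background=background,
                )
            )
    return specs


def generate_benchmark(
    hierarchy: list[FamilySpec],
    n_nonenzymes: int,
    seed: int,
    fasta_path: str | Path | None = None,
    annotations_path: str | Path | None = None,
) -> list[ProteinRecord]:
    """Full toy proteome: every family plus motif-free non-enzymes.

    Child-family members carry both parent and own motifs by construction of
    the specs.  Optionally writes the FASTA and annotation TSV that the
    dataset builder consumes.
    """
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    for spec in hierarchy:
        records.extend(generate_family(spec, seed=int(rng.integers(2**31))))
    length_range = hierarchy[0].length_range if hierarchy else (120, 400)
    background = hierarchy[0].background if hierarchy else UNIFORM_COMPOSITION
    for i in range(n_nonenzymes):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = _background(rng, length, background)
        records.append(
            ProteinRecord(
                id=f"nonenz_{i:04d}",
                sequence="".join(AMINO_ACIDS[c] for c in seq),
                ec_annotations=set(),
                annotation_score=5,
                is_enzyme=False,
            )
        )
    if fasta_path is not None:
        write_fasta(records, fasta_path)
    if annotations_path is not None:
        write_annotation_table(records, annotations_path)
    return records
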