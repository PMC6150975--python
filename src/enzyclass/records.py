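"""Protein records and prediction results."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .ec import ECNumber

__all__ = ["ProteinRecord", "PredictionResult", "sanitize_sequence", "AMINO_ACIDS"]

#: canonical 20-letter amino-acid alphabet, the fixed feature ordering used
#: throughout (profile matrices, composition vectors).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL = set(AMINO_ACIDS)
#: ambiguous / rare letters that are mapped to X under the default policy
_NON_CANONICAL = set("BZXUOJ")


def sanitize_sequence(sequence: str, *, policy: str = "mask", name: str = "") -> str:
    """Validate an amino-acid sequence.

    policy "mask" (default) maps non-canonical letters (B, Z, X, U, O, J) to X;
    policy "strict" raises on any non-canonical letter.  Anything outside both
    sets is always an error.  X-containing subsequence windows are later
    excluded from profile construction and X contributes nothing to
    physicochemical descriptors, so the masked sequence stays numerically
    well-defined.
    """
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError(f"empty sequence{' for ' + name if name else ''}")
    out = []
    for i, ch in enumerate(seq):
        if ch in _CANONICAL:
            out.append(ch)
        elif ch in _NON_CANONICAL:
            if policy == "strict":
                raise ValueError(
                    f"non-canonical residue {ch!r} at position {i + 1}"
                    f"{' in record ' + name if name else ''}"
                )
            out.append("X")
        else:
            raise ValueError(
                f"invalid residue {ch!r} at position {i + 1}"
                f"{' in record ' + name if name else ''}"
            )
    return "".join(out)


@dataclass
class ProteinRecord:
    """One protein sequence with optional functional annotation.

    ``annotation_score`` mirrors the 1-5 star reliability rating curated
    databases attach to entries; non-enzymes admitted to negative training
    pools must carry >= 4 stars.  ``is_enzyme`` may be None (unknown).
    """

    id: str
    sequence: str
    ec_annotations: set[ECNumber] = field(default_factory=set)
    annotation_score: int | None = None
    is_enzyme: bool | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.id}")
        if self.annotation_score is not None and self.annotation_score not in (
            1,
            2,
            3,
            4,
            5,
        ):
            raise ValueError(
                f"annotation_score must be 1-5, got {self.annotation_score}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PredictionResult:
    """Traversal outcome for one query.

    ``label`` is either a full EC path string (possibly with trailing "-"),
    "non-enzyme" (all main-class scores below the negative cutoff) or
    "no prediction" (ambiguous scores between the cutoffs).  ``confidence``
    is the weighted ensemble score of the deepest accepted class.
    ``per_level_scores`` keeps the accepted (EC, score) per level for audit.
    """

    protein_id: str
    label: str
    confidence: float = 0.0
    per_level_scores: dict[int, tuple[ECNumber, float]] = field(default_factory=dict)

    NON_ENZYME = "non-enzyme"
    NO_PREDICTION = "no prediction"

    @property
    def is_enzyme_prediction(self) -> bool:
        return self.label not in (self.NON_ENZYME, self.NO_PREDICTION)

    @property
    def predicted_ec(self) -> ECNumber | None:
        if not self.is_enzyme_prediction:
            return None
        from .ec import parse_ec

        return parse_ec(self.label)


def warn_once(message: str) -> None:
    warnings.warn(message, stacklevel=3)
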