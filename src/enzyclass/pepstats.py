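"""Peptide-statistics descriptors (EMBOSS Pepstats style) and scaling.

Every protein is summarized by a 37-dimensional composition-based vector:

* 20 amino-acid mole percentages (alphabetical one-letter order A..Y);
* 9 physicochemical-class mole percentages — tiny, small, aliphatic,
  aromatic, non-polar, polar, charged, basic, acidic — using the classic
  EMBOSS property groupings restricted to the 20 canonical residues;
* 8 whole-protein quantities: molecular weight (Da), residue count, average
  residue weight (Da), net charge at pH 7, isoelectric point, molar
  extinction coefficient reduced and with cystine bridges (M^-1 cm^-1), and
  extinction at 1 mg/ml (reduced, A_280 for a 1 mg/ml solution).

The net charge model is the usual Henderson-Hasselbalch sum over the ionizable
groups (N/C termini, K, R, H positive side; D, E, C, Y negative side) with the
EMBOSS pK values below; pI is found by bisection of the monotone charge-pH
curve to |charge| < 1e-4.  X residues contribute only to the residue count
and the average-weight denominator is the canonical residue count, so masked
sequences stay well defined.

All 37 features depend on composition only, never on residue order.
"""

from __future__ import annotations

import numpy as np

from .records import AMINO_ACIDS

__all__ = [
    "FEATURE_NAMES",
    "pepstats_features",
    "net_charge",
    "isoelectric_point",
    "MinMaxScaler37",
    "fit_scaler",
    "apply_scaler",
]

# EMBOSS-style pK values of ionizable groups
PK = {
    "Nterm": 8.6,
    "Cterm": 3.6,
    "K": 10.8,
    "R": 12.5,
    "H": 6.5,
    "D": 3.9,
    "E": 4.1,
    "C": 8.5,
    "Y": 10.1,
}

# average residue (monomer minus water) masses, Da
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01524

# EMBOSS property groupings, canonical residues only
PROPERTY_CLASSES = {
    "tiny": "ACGST",
    "small": "ACDGNPSTV",
    "aliphatic": "AILV",
    "aromatic": "FHWY",
    "non_polar": "ACFGILMPVWY",
    "polar": "DEHKNQRST",
    "charged": "DEHKR",
    "basic": "HKR",
    "acidic": "DE",
}

# molar extinction contributions at 280 nm (Pace values)
EXTINCTION_W = 5500.0
EXTINCTION_Y = 1490.0
EXTINCTION_CYSTINE = 125.0

FEATURE_NAMES: list[str] = (
    [f"mole_percent_{a}" for a in AMINO_ACIDS]
    + [f"mole_percent_{c}" for c in PROPERTY_CLASSES]
    + [
        "molecular_weight",
        "residue_count",
        "average_residue_weight",
        "charge_ph7",
        "isoelectric_point",
        "extinction_molar_reduced",
        "extinction_molar_cystine",
        "extinction_1mgml_reduced",
    ]
)
assert len(FEATURE_NAMES) == 37


def _counts(sequence: str) -> dict[str, int]:
    counts = {a: 0 for a in AMINO_ACIDS}
    for ch in sequence:
        if ch in counts:
            counts[ch] += 1
    return counts


def net_charge(sequence: str, ph: float) -> float:
    """Net charge at the given pH (Henderson-Hasselbalch over ionizable groups)."""
    if not sequence:
        raise ValueError("empty sequence")
    counts = _counts(sequence)
    positive = [("Nterm", 1), ("K", counts["K"]), ("R", counts["R"]), ("H", counts["H"])]
    negative = [("Cterm", 1), ("D", counts["D"]), ("E", counts["E"]),
                ("C", counts["C"]), ("Y", counts["Y"])]
    charge = 0.0
    for group, n in positive:
        charge += n / (1.0 + 10.0 ** (ph - PK[group]))
    for group, n in negative:
        charge -= n / (1.0 + 10.0 ** (PK[group] - ph))
    return charge


def isoelectric_point(sequence: str, tol: float = 1e-4) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14]."""
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        charge = net_charge(sequence, mid)
        if abs(charge) < tol:
            return mid
        if charge > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def pepstats_features(sequence: str) -> np.ndarray:
    """The 37-entry descriptor vector for one sequence (see module docstring)."""
    if not sequence:
        raise ValueError("empty sequence")
    counts = _counts(sequence)
    n_canonical = sum(counts.values())
    n_total = len(sequence)
    if n_canonical == 0:
        raise ValueError("sequence contains no canonical residue")

    mole = {a: 100.0 * counts[a] / n_canonical for a in AMINO_ACIDS}
    class_mole = [
        sum(mole[a] for a in members) for members in PROPERTY_CLASSES.values()
    ]

    mw = sum(counts[a] * RESIDUE_MASS[a] for a in AMINO_ACIDS) + WATER_MASS
    avg_residue_weight = (mw - WATER_MASS) / n_canonical
    charge7 = net_charge(sequence, 7.0)
    pi = isoelectric_point(sequence)
    ext_reduced = counts["W"] * EXTINCTION_W + counts["Y"] * EXTINCTION_Y
    ext_cystine = ext_reduced + (counts["C"] // 2) * EXTINCTION_CYSTINE
    ext_1mgml = ext_reduced / mw

    vec = (
        [mole[a] for a in AMINO_ACIDS]
        + class_mole
        + [mw, float(n_total), avg_residue_weight, charge7, pi,
           ext_reduced, ext_cystine, ext_1mgml]
    )
    return np.array(vec, dtype=float)


def pepstats_features_many(sequences) -> np.ndarray:
    return np.vstack([pepstats_features(s) for s in sequences])


class MinMaxScaler37:
    """Per-dimension min-max scaling fit on training vectors only.

    Out-of-range values (validation/test) are clipped into [0, 1]; a constant
    training dimension maps everything to 0.
    """

    def __init__(self, minima: np.ndarray, span: np.ndarray) -> None:
        self.minima = minima
        self.span = span  # 0 marks a constant dimension

    def transform(self, vectors: np.ndarray) -> np.ndarray:
        vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
        out = np.zeros_like(vectors)
        nonconst = self.span > 0
        out[:, nonconst] = (vectors[:, nonconst] - self.minima[nonconst]) / self.span[
            nonconst
        ]
        return np.clip(out, 0.0, 1.0)


def fit_scaler(train_vectors: np.ndarray) -> MinMaxScaler37:
    train_vectors = np.atleast_2d(np.asarray(train_vectors, dtype=float))
    if train_vectors.shape[0] < 1:
        raise ValueError("need at least one training vector")
    minima = train_vectors.min(axis=0)
    span = train_vectors.max(axis=0) - minima
    return MinMaxScaler37(minima, span)


def apply_scaler(scaler: MinMaxScaler37, vector: np.ndarray) -> np.ndarray:
    return scaler.transform(vector)[0] if np.asarray(vector).ndim == 1 else scaler.transform(vector)
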