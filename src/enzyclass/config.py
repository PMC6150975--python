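"""Run configuration: every tunable with its default, plus a plain-text format."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All pipeline tunables.

    Serializes to/from a simple ``key = value`` text file; unknown keys are
    rejected.  The negative mixes are (sibling-branch, other-main,
    non-enzyme) fractions; ``wne`` zeroes the non-enzyme fraction (the
    "without non-enzymes" ablation).
    """

    l: int = 5                      # subsequence window length
    t: int = 8                      # window clustering similarity threshold
    k: int = 5                      # kNN neighbourhood size
    folds: int = 5                  # cross-validation folds
    discard_fraction: float = 0.10  # min cluster size / positive proteins
    min_class_size: int = 50        # class eligibility threshold
    identity_threshold: float = 0.5 # redundancy clustering identity
    val_fraction: float = 0.1       # cluster fraction held out for validation
    negative_cutoff: float = 0.3    # global non-enzyme rejection cutoff
    main_mix: tuple[float, float, float] = (0.0, 0.5, 0.5)
    sublevel_mix: tuple[float, float, float] = (0.5, 0.25, 0.25)
    seed: int = 42
    wne: bool = False               # drop non-enzymes from negative sets
    svm_c: float = 1.0
    svm_gamma: str = "scale"
    representatives_only: bool = True

    def __post_init__(self) -> None:
        for name in ("main_mix", "sublevel_mix"):
            mix = tuple(getattr(self, name))
            if len(mix) != 3 or abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be three fractions summing to 1")
            setattr(self, name, mix)
        if self.wne:
            self.main_mix = _drop_nonenzymes(self.main_mix)
            self.sublevel_mix = _drop_nonenzymes(self.sublevel_mix)

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in fields(self):
            value = getattr(self, f.name)
            if isinstance(value, tuple):
                value = ",".join(str(v) for v in value)
            lines.append(f"{f.name} = {value}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        known = {f.name: f for f in fields(cls)}
        kwargs: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected 'key = value'")
            key, _, value = (s.strip() for s in line.partition("="))
            if key not in known:
                raise ValueError(f"line {lineno}: unknown config key {key!r}")
            kwargs[key] = _parse_value(key, value)
        return cls(**kwargs)

    def as_dict(self) -> dict:
        return asdict(self)


def _drop_nonenzymes(mix: tuple[float, float, float]) -> tuple[float, float, float]:
    sib, other, _ = mix
    enz = sib + other
    if enz == 0:
        return (0.0, 1.0, 0.0)
    return (sib / enz, other / enz, 0.0)


def _parse_value(key: str, value: str):
    if key in ("main_mix", "sublevel_mix"):
        return tuple(float(v) for v in value.split(","))
    if key in ("wne", "representatives_only"):
        return value.lower() in ("1", "true", "yes")
    if key in ("l", "t", "k", "folds", "min_class_size", "seed"):
        return int(value)
    if key == "svm_gamma":
        try:
            return float(value)
        except ValueError:
            return value
    return float(value)
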