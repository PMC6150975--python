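"""EC-number algebra.

An Enzyme Commission (EC) number is a four-component hierarchical identifier
(main class . subclass . sub-subclass . substrate).  Trailing components may be
unspecified, written "-"; e.g. ``1.1.-.-`` denotes the subclass node "acting on
the CH-OH group of donors" below main class 1 (oxidoreductases).  The *level*
of an EC number is the count of specified components (1-4); level 0 denotes
the enzyme/non-enzyme gate and has no EC representation.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import total_ordering
from typing import Iterable

__all__ = ["ECNumber", "parse_ec", "ec_relations"]

WILDCARD = "-"


@total_ordering
@dataclass(frozen=True)
class ECNumber:
    """A node in the 4-level EC tree.

    ``components`` is a 4-tuple of positive ints with ``None`` standing for the
    "-" wildcard; wildcards are suffix-only (no numeric component may follow a
    wildcard).
    """

    components: tuple[int | None, int | None, int | None, int | None]

    def __post_init__(self) -> None:
        comps = self.components
        if len(comps) != 4:
            raise ValueError(f"EC number needs 4 components, got {len(comps)}")
        seen_wild = False
        for c in comps:
            if c is None:
                seen_wild = True
            else:
                if seen_wild:
                    raise ValueError(
                        f"numeric component after wildcard in {comps!r}"
                    )
                if not isinstance(c, int) or c <= 0:
                    raise ValueError(f"EC components must be positive ints: {c!r}")

    @property
    def level(self) -> int:
        """Number of specified components (1 for a main class, 4 for a leaf)."""
        return sum(c is not None for c in self.components)

    @property
    def numeric(self) -> tuple[int, ...]:
        """The specified (non-wildcard) prefix."""
        return tuple(c for c in self.components if c is not None)

    @property
    def main_class(self) -> int:
        return self.components[0]  # type: ignore[return-value]

    def __str__(self) -> str:
        return ".".join(WILDCARD if c is None else str(c) for c in self.components)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ECNumber({self})"

    def __lt__(self, other: "ECNumber") -> bool:
        key = tuple(-1 if c is None else c for c in self.components)
        okey = tuple(-1 if c is None else c for c in other.components)
        return (self.level, key) < (other.level, okey)

    # -- hierarchy algebra ------------------------------------------------

    def parent(self) -> "ECNumber | None":
        """The node one level up, or None for a main class."""
        lvl = self.level
        if lvl <= 1:
            return None
        comps = list(self.components)
        comps[lvl - 1] = None
        return ECNumber(tuple(comps))

    def ancestors(self) -> list["ECNumber"]:
        """All proper ancestors, nearest first."""
        out = []
        node = self.parent()
        while node is not None:
            out.append(node)
            node = node.parent()
        return out

    def truncate(self, level: int) -> "ECNumber | None":
        """This EC cut to the given level; None if level exceeds this node's."""
        if level < 1 or level > self.level:
            return None
        comps: list[int | None] = list(self.numeric[:level])
        comps += [None] * (4 - level)
        return ECNumber(tuple(comps))

    def is_ancestor_of(self, other: "ECNumber") -> bool:
        a, b = self.numeric, other.numeric
        return len(a) < len(b) and b[: len(a)] == a

    def is_child_of(self, other: "ECNumber") -> bool:
        return other.is_ancestor_of(self) and self.level == other.level + 1


def parse_ec(text: str) -> ECNumber:
    """Parse ``"1.1.2.4"`` / ``"2.-.-.-"`` style strings into an :class:`ECNumber`.

    Raises ``ValueError`` on a wrong token count, a numeric component after a
    wildcard, or a non-numeric token.
    """
    tokens = text.strip().split(".")
    if len(tokens) != 4:
        raise ValueError(f"expected 4 dot-separated components: {text!r}")
    comps: list[int | None] = []
    for tok in tokens:
        if tok == WILDCARD:
            comps.append(None)
        elif tok.isdigit() and int(tok) > 0:
            comps.append(int(tok))
        else:
            raise ValueError(f"bad EC component {tok!r} in {text!r}")
    return ECNumber(tuple(comps))


def ec_relations(a: ECNumber, b: ECNumber) -> str:
    """Relation of ``a`` to ``b``: self / ancestor / descendant / sibling / unrelated.

    ``ancestor`` means a's specified prefix is a proper prefix of b's; ``sibling``
    means same level, same parent, different last component.
    """
    na, nb = a.numeric, b.numeric
    if na == nb:
        return "self"
    if a.is_ancestor_of(b):
        return "ancestor"
    if b.is_ancestor_of(a):
        return "descendant"
    if len(na) == len(nb) and na[:-1] == nb[:-1]:
        return "sibling"
    return "unrelated"


def sort_ec(ecs: Iterable[ECNumber]) -> list[ECNumber]:
    """Sort by level then lexicographically on components."""
    return sorted(ecs)
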