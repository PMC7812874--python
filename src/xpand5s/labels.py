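"""Universal 5S rRNA position labels.

Residues of the conserved core carry integer labels on the E. coli-anchored
scale (1..120); residues absent from the archetype carry decimal-fraction
labels that extend the nearest upstream core position (89.1, 104.1, and for
insertions nested after such a column, 104.1.1 and so on).  Labels order
5'->3' along the molecule: a prefix sorts before any of its extensions, and
extensions sort by their first differing index.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass


class LabelError(ValueError):
    """Raised for malformed position-label text."""


@functools.total_ordering
@dataclass(frozen=True)
class PositionLabel:
    """A dotted position label in the universal 5S numbering.

    ``parts[0]`` is the core position; subsequent elements are insertion
    indices at successive nesting depths.
    """

    parts: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.parts:
            raise LabelError("empty position label")
        if any((not isinstance(p, int)) or p < 1 for p in self.parts):
            raise LabelError(f"label parts must be positive integers: {self.parts!r}")
        object.__setattr__(self, "parts", tuple(self.parts))

    @property
    def core(self) -> int:
        """Core position this label is anchored to."""
        return self.parts[0]

    @property
    def is_core(self) -> bool:
        return len(self.parts) == 1

    def extend(self, index: int) -> "PositionLabel":
        """Label of the ``index``-th inserted residue nested under this one."""
        return PositionLabel(self.parts + (index,))

    def __str__(self) -> str:
        return ".".join(str(p) for p in self.parts)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PositionLabel({self})"

    def __lt__(self, other: "PositionLabel") -> bool:
        if not isinstance(other, PositionLabel):
            return NotImplemented
        # Lexicographic on parts; a shorter prefix precedes its extensions.
        return self.parts < other.parts


def parse_position_label(text: str) -> PositionLabel:
    """Parse a dotted label such as ``"52"``, ``"89.1"`` or ``"104.1.2"``.

    Round trip: ``str(parse_position_label(t)) == t`` for any valid ``t``.
    """
    if not isinstance(text, str) or not text:
        raise LabelError("empty position label")
    parts = []
    for piece in text.split("."):
        if not piece.isdigit():
            raise LabelError(f"non-integer label part {piece!r} in {text!r}")
        value = int(piece)
        if value < 1 or (piece != str(value)):
            raise LabelError(f"invalid label part {piece!r} in {text!r}")
        parts.append(value)
    return PositionLabel(tuple(parts))


def compare_labels(a: PositionLabel, b: PositionLabel) -> int:
    """Three-way comparison: -1, 0 or 1 as ``a`` precedes, equals or follows ``b``."""
    if a.parts == b.parts:
        return 0
    return -1 if a.parts < b.parts else 1
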