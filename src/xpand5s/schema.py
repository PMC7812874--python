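"""Core schemas for bacterial and archaeal 5S rRNA.

A :class:`CoreSchema` is the ordered list of universally numbered columns
(label, consensus code, conserved flag, secondary-structure element)
together with landmark base pairs (G7-C113 in helix I; the U77-A99 and
A78-G98 interactions bracketing helix IV), the three anchor fragments used
for seeding core alignments, and a concrete reference sequence realising
the schema one residue per column.

Two schemas ship with the package: ``bacterial`` (E. coli archetype) and
``archaeal`` (a constructed Halobacterium-type fixture carrying the
archaea-specific columns 76.1 — the loop E bulge — and 104.1).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache

import yaml

from .iupac import expansion, matches_pattern
from .labels import PositionLabel, parse_position_label

ELEMENTS = frozenset(
    ["helixI", "loopA", "helixII", "loopB", "helixIII", "loopC", "loopE",
     "helixIV", "loopD", "helixV", "junction"]
)


class SchemaError(ValueError):
    pass


@dataclass(frozen=True)
class SchemaColumn:
    label: PositionLabel
    consensus: str
    conserved: bool
    element: str


@dataclass(frozen=True)
class CoreSchema:
    variant: str
    columns: tuple[SchemaColumn, ...]
    landmarks: tuple[tuple[PositionLabel, PositionLabel], ...]
    anchors: tuple[tuple[PositionLabel, PositionLabel], ...]
    reference_sequence: str
    reference_id: str
    description: str = ""
    _index: dict[PositionLabel, int] = field(default_factory=dict, repr=False,
                                             compare=False)

    def __post_init__(self) -> None:
        if self.variant not in ("bacterial", "archaeal"):
            raise SchemaError(f"unknown schema variant {self.variant!r}")
        labels = [c.label for c in self.columns]
        if any(b <= a for a, b in zip(labels, labels[1:])):
            raise SchemaError("schema labels must be strictly increasing")
        if len(self.reference_sequence) != len(self.columns):
            raise SchemaError("reference sequence does not realise the columns")
        for col, base in zip(self.columns, self.reference_sequence):
            if base not in expansion(col.consensus):
                raise SchemaError(
                    f"reference base {base} at {col.label} violates consensus "
                    f"{col.consensus}")
            if col.element not in ELEMENTS:
                raise SchemaError(f"unknown element {col.element!r}")
        object.__setattr__(self, "_index", {l: i for i, l in enumerate(labels)})

    # -- lookups -----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.columns)

    @property
    def labels(self) -> tuple[PositionLabel, ...]:
        return tuple(c.label for c in self.columns)

    def index_of(self, label: PositionLabel) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise SchemaError(
                f"label {label} not present in {self.variant} schema") from None

    def has_label(self, label: PositionLabel) -> bool:
        return label in self._index

    def anchor_fragments(self) -> list[tuple[int, int, str]]:
        """(start, end, fragment) per anchor window, on reference offsets."""
        out = []
        for lo, hi in self.anchors:
            i, j = self.index_of(lo), self.index_of(hi) + 1
            out.append((i, j, self.reference_sequence[i:j]))
        return out

    def consensus_string(self) -> str:
        return "".join(c.consensus for c in self.columns)


def _parse_label_pair(pair: list[str]) -> tuple[PositionLabel, PositionLabel]:
    a, b = pair
    return (parse_position_label(str(a)), parse_position_label(str(b)))


def schema_from_dict(doc: dict) -> CoreSchema:
    columns = tuple(
        SchemaColumn(
            label=parse_position_label(str(c["label"])),
            consensus=str(c["consensus"]).upper().replace("T", "U"),
            conserved=bool(c["conserved"]),
            element=str(c["element"]),
        )
        for c in doc["columns"]
    )
    return CoreSchema(
        variant=doc["variant"],
        columns=columns,
        landmarks=tuple(_parse_label_pair(p) for p in doc["landmarks"]),
        anchors=tuple(_parse_label_pair(p) for p in doc["anchors"]),
        reference_sequence=str(doc["reference_sequence"]).upper().replace("T", "U"),
        reference_id=str(doc.get("reference_id", "reference")),
        description=str(doc.get("description", "")),
    )


@lru_cache(maxsize=None)
def load_schema(variant: str) -> CoreSchema:
    """Load a packaged schema: ``"bacterial"`` or ``"archaeal"``."""
    name = {"bacterial": "bacterial_schema.yaml",
            "archaeal": "archaeal_schema.yaml"}.get(variant)
    if name is None:
        raise SchemaError(f"unknown schema variant {variant!r}")
    text = importlib.resources.files("xpand5s.data").joinpath(name).read_text()
    return schema_from_dict(yaml.safe_load(text))


def load_schema_file(path) -> CoreSchema:
    with open(path) as fh:
        return schema_from_dict(yaml.safe_load(fh))
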