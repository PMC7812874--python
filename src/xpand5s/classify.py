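"""Structural typing and catalog summaries.

A *structural type* is operationalised as the class of molecules sharing an
insertion-site signature (the multiset of universal-numbering sites over a
molecule's segments).  Within a type, molecules are further grouped into
subtypes by single-linkage clustering on pairwise global sequence identity
of their (site-ordered, concatenated) segments — the published
thermoanaerobacterial type, for instance, splits into three such subtype
families.  The identity denominator is the shorter sequence, since segments
of one family vary in length.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .labels import PositionLabel, parse_position_label
from .numbering import ExpansionSegment
from .pairwise import global_identity


@dataclass(frozen=True)
class Molecule:
    """One 5S rRNA molecule and its expansion segments."""

    record_id: str
    taxon: str
    segments: tuple[ExpansionSegment, ...]

    @property
    def site_signature(self) -> tuple[str, ...]:
        return tuple(sorted((s.site_str for s in self.segments),
                            key=_site_sort_key))

    @property
    def concatenated(self) -> str:
        ordered = sorted(self.segments,
                         key=lambda s: (s.site[0], s.site[1], s.start))
        return "".join(s.sequence for s in ordered)


def _site_sort_key(site: str) -> tuple:
    a, b = site.split("-")
    return (parse_position_label(a), parse_position_label(b))


@dataclass(frozen=True)
class StructuralType:
    type_id: str
    site_signature: tuple[str, ...]
    members: tuple[Molecule, ...]
    subtypes: tuple[tuple[str, ...], ...]   # record-id groups, single linkage
    exemplar: str                           # lexicographically smallest concat


def classify_structural_types(molecules: list[Molecule],
                              identity_threshold: float = 0.6
                              ) -> list[StructuralType]:
    """Group molecules into structural types and subtype clusters.

    Deterministic and order-independent: types are ordered by (first site,
    exemplar sequence); members and subtype groups are sorted internally.
    """
    by_sig: dict[tuple[str, ...], list[Molecule]] = {}
    for mol in molecules:
        if not mol.segments:
            continue
        by_sig.setdefault(mol.site_signature, []).append(mol)

    types: list[StructuralType] = []
    for sig, members in by_sig.items():
        members = sorted(members, key=lambda m: (m.concatenated, m.record_id))
        exemplar = members[0].concatenated
        subtypes = _single_linkage(members, identity_threshold)
        types.append(StructuralType(
            type_id="", site_signature=sig, members=tuple(members),
            subtypes=subtypes, exemplar=exemplar))
    types.sort(key=lambda t: (_site_sort_key(t.site_signature[0]),
                              t.site_signature, t.exemplar))
    return [StructuralType(type_id=f"T{i + 1:02d}", site_signature=t.site_signature,
                           members=t.members, subtypes=t.subtypes,
                           exemplar=t.exemplar)
            for i, t in enumerate(types)]


def _single_linkage(members: list[Molecule], threshold: float
                    ) -> tuple[tuple[str, ...], ...]:
    n = len(members)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            ident = global_identity(members[i].concatenated,
                                    members[j].concatenated,
                                    denominator="shorter")
            if ident >= threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list[str]] = {}
    for i, m in enumerate(members):
        groups.setdefault(find(i), []).append(m.record_id)
    out = [tuple(sorted(g)) for g in groups.values()]
    out.sort()
    return tuple(out)


# ---------------------------------------------------------------------------
# catalog frame and summary
# ---------------------------------------------------------------------------

CATALOG_COLUMNS = ["record", "taxon", "site", "length", "sequence", "type"]


def catalog_frame(molecules: list[Molecule],
                  types: list[StructuralType] | None = None) -> pd.DataFrame:
    """One catalog row per expansion segment."""
    type_of: dict[str, str] = {}
    if types:
        for t in types:
            for m in t.members:
                type_of[m.record_id] = t.type_id
    rows = []
    for mol in molecules:
        for seg in sorted(mol.segments, key=lambda s: s.start):
            rows.append({
                "record": mol.record_id,
                "taxon": mol.taxon,
                "site": seg.site_str,
                "length": seg.length,
                "sequence": seg.sequence,
                "type": type_of.get(mol.record_id, ""),
            })
    return pd.DataFrame(rows, columns=CATALOG_COLUMNS)


def read_catalog(path) -> pd.DataFrame:
    """Ingest a catalog TSV (e.g. an exported supplementary table)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = {"record", "site", "length"} - set(df.columns)
    if missing:
        raise ValueError(f"catalog missing columns: {sorted(missing)}")
    df["length"] = df["length"].astype(int)
    for col in CATALOG_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    return df[CATALOG_COLUMNS]


def write_catalog(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def summarize_catalog(catalog: pd.DataFrame) -> dict:
    """Exact counts over a segment catalog.

    Returns molecule/segment/site/type counts, length extrema, and per-site
    and per-taxon breakdowns.  Idempotent: a function of the catalog only.
    """
    if catalog.empty:
        return {
            "n_segments": 0, "n_molecules": 0, "n_taxa": 0, "n_sites": 0,
            "n_types": 0, "length_min": 0, "length_max": 0,
            "segments_per_molecule_max": 0,
            "per_site": {}, "per_taxon": {},
        }
    per_mol = catalog.groupby("record").size()
    return {
        "n_segments": int(len(catalog)),
        "n_molecules": int(catalog["record"].nunique()),
        "n_taxa": int(catalog.loc[catalog["taxon"] != "", "taxon"].nunique()),
        "n_sites": int(catalog["site"].nunique()),
        "n_types": int(catalog.loc[catalog["type"] != "", "type"].nunique()),
        "length_min": int(catalog["length"].min()),
        "length_max": int(catalog["length"].max()),
        "segments_per_molecule_max": int(per_mol.max()),
        "per_site": {k: int(v) for k, v in
                     catalog.groupby("site").size().sort_index().items()},
        "per_taxon": {k: int(v) for k, v in
                      catalog.groupby("taxon").size().sort_index().items()
                      if k != ""},
    }


def summary_text(summary: dict) -> str:
    lines = [
        "Expansion segment catalog summary",
        f"  segments:            {summary['n_segments']}",
        f"  molecules:           {summary['n_molecules']}",
        f"  taxa:                {summary['n_taxa']}",
        f"  distinct sites:      {summary['n_sites']}",
        f"  structural types:    {summary['n_types']}",
        f"  segment length:      {summary['length_min']}-{summary['length_max']} nt",
        f"  max segments/molecule: {summary['segments_per_molecule_max']}",
        "  per site:",
    ]
    for site, n in summary["per_site"].items():
        lines.append(f"    {site}: {n}")
    return "\n".join(lines) + "\n"
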