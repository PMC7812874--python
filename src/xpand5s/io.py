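"""FASTA and GFF3/TSV input-output.

Coordinates are 0-based half-open internally and in TSV/BED output; GFF3 is
1-based inclusive, converted at this boundary (both conventions are stated
in the file headers).  Sequences are normalised to uppercase RNA (U) in
memory; the FASTA writer restores the alphabet the record came in with.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .iupac import normalize


class FormatError(ValueError):
    pass


@dataclass
class Record:
    """A sequence record; ``seq`` is uppercase RNA, ``dna`` remembers
    whether the source used T so round trips preserve the alphabet."""

    id: str
    seq: str
    description: str = ""
    dna: bool = False

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def output_seq(self) -> str:
        return self.seq.replace("U", "T") if self.dna else self.seq


def read_fasta(path) -> list[Record]:
    """Read FASTA records; case-insensitive, T/U both accepted."""
    path = Path(path)
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            raw = str(rec.seq)
            if not raw:
                raise FormatError(f"empty sequence for record {rec.id!r}")
            records.append(Record(
                id=rec.id, seq=normalize(raw),
                description=rec.description,
                dna=("T" in raw.upper()) and ("U" not in raw.upper()),
            ))
    except FileNotFoundError:
        raise
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: list[Record], path, width: int = 70) -> None:
    seqrecords = [
        SeqRecord(Seq(r.output_seq), id=r.id,
                  description=r.description[len(r.id):].strip()
                  if r.description.startswith(r.id) else r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecords)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Feature:
    """A genomic feature on 0-based half-open internal coordinates."""

    seqid: str
    ftype: str
    start: int      # 0-based half-open
    end: int
    strand: str = "+"
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(f"invalid feature span {self.start}..{self.end}")


GFF_HEADER = ("##gff-version 3\n"
              "# coordinates below are 1-based inclusive (GFF3 convention); "
              "the package uses 0-based half-open internally\n")


def _fmt_attrs(attrs: dict) -> str:
    if not attrs:
        return "."
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def write_gff3(features: list[Feature], path, source: str = "xpand5s") -> None:
    with open(path, "w") as fh:
        fh.write(GFF_HEADER)
        for f in features:
            fh.write("\t".join([
                f.seqid, source, f.ftype,
                str(f.start + 1), str(f.end),   # to 1-based inclusive
                ".", f.strand, ".", _fmt_attrs(f.attributes),
            ]) + "\n")


def read_gff3(path) -> list[Feature]:
    features = []
    for raw in Path(path).read_text().splitlines():
        if not raw or raw.startswith("#"):
            continue
        parts = raw.split("\t")
        if len(parts) != 9:
            raise FormatError(f"malformed GFF3 line: {raw!r}")
        attrs = {}
        if parts[8] != ".":
            for item in parts[8].split(";"):
                if item:
                    k, _, v = item.partition("=")
                    attrs[k] = v
        features.append(Feature(
            seqid=parts[0], ftype=parts[2],
            start=int(parts[3]) - 1, end=int(parts[4]),  # back to half-open
            strand=parts[6], attributes=attrs,
        ))
    return features


def span_length_1based(start: int, end: int) -> int:
    """Length of a printed 1-based inclusive span such as GenBank's
    84899..85053."""
    if end < start or start < 1:
        raise FormatError(f"invalid 1-based span {start}..{end}")
    return end - start + 1


# ---------------------------------------------------------------------------
# catalog annotation export
# ---------------------------------------------------------------------------

def annotation_features(molecules, gene_spans: dict[str, tuple[str, int, int, str]]
                        ) -> list[Feature]:
    """GFF3 features for annotated molecules: a gene parent per molecule
    plus one expansion_segment child per segment.

    ``gene_spans`` maps record id -> (genome seqid, start, end, strand) on
    0-based half-open genome coordinates; molecules without an entry are
    emitted on their own record coordinate system.
    """
    feats: list[Feature] = []
    for mol in molecules:
        span = gene_spans.get(mol.record_id)
        if span is None:
            seqid, g0, strand = mol.record_id, 0, "+"
            g1 = g0 + (max((s.start + s.length for s in mol.segments),
                           default=1))
        else:
            seqid, g0, g1, strand = span
        feats.append(Feature(seqid=seqid, ftype="gene", start=g0, end=g1,
                             strand=strand,
                             attributes={"ID": mol.record_id}))
        for i, seg in enumerate(sorted(mol.segments, key=lambda s: s.start), 1):
            if strand == "-":
                s0 = g1 - (seg.start + seg.length)
                s1 = g1 - seg.start
            else:
                s0 = g0 + seg.start
                s1 = g0 + seg.start + seg.length
            feats.append(Feature(
                seqid=seqid, ftype="expansion_segment", start=s0, end=s1,
                strand=strand,
                attributes={"ID": f"{mol.record_id}.seg{i}",
                            "Parent": mol.record_id,
                            "site": seg.site_str,
                            "length": str(seg.length)}))
    return feats


def write_annotations(molecules, types, out_dir,
                      gene_spans: dict | None = None) -> dict[str, Path]:
    """Write the catalog TSV and GFF3 for a set of annotated molecules.

    Returns the paths written.  Deterministic given its inputs.
    """
    from .classify import catalog_frame, write_catalog

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    catalog = catalog_frame(molecules, types)
    tsv = out_dir / "catalog.tsv"
    write_catalog(catalog, tsv)
    gff = out_dir / "annotations.gff3"
    write_gff3(annotation_features(molecules, gene_spans or {}), gff)
    return {"catalog": tsv, "gff3": gff}
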