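"""Seeded synthetic genomes with ground truth.

The generator emulates the discovery scenarios of the genomic screen:
normal 5S genes (~120 nt), expanded genes carrying 1-3 hairpin-type
insertions of 13-109 nt at conserved-core sites, pseudogene remnants
missing both termini but retaining an insertion, chimeric half-and-half
sequences, and internal tandem duplications — all embedded in random
intergenic background on either strand, with a complete coordinate ledger.

Randomness: a single integer seed drives a named stream per generator
stage (and per feature index), so adding stages never perturbs earlier
outputs and every artefact is reproducible bit-for-bit.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .iupac import reverse_complement
from .labels import PositionLabel, parse_position_label
from .numbering import CoreAlignmentMap
from .schema import CoreSchema, load_schema

BASES = np.array(list("ACGU"))
PAIRS = [("G", "C"), ("C", "G"), ("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")]


def stream(seed: int, stage: str, index: int = 0) -> np.random.Generator:
    """Named, order-independent pseudorandom stream."""
    return np.random.default_rng([seed & 0x7FFFFFFF,
                                  zlib.crc32(stage.encode()), index])


# ---------------------------------------------------------------------------
# gene-level generators
# ---------------------------------------------------------------------------

def generate_core_gene(schema: CoreSchema, mutation_rate: float,
                       seed: int, index: int = 0) -> tuple[str, list[int]]:
    """Reference sequence with seeded substitutions at non-conserved
    columns only (conserved columns, which include all anchor fragments and
    landmarks, are never mutated).  Returns (sequence, mutated offsets)."""
    if not (0.0 <= mutation_rate <= 0.2):
        raise ValueError("mutation_rate must lie in [0, 0.2]")
    rng = stream(seed, "core_gene", index)
    seq = list(schema.reference_sequence)
    mutated = []
    for i, col in enumerate(schema.columns):
        if col.conserved:
            continue
        if rng.random() < mutation_rate:
            alternatives = [b for b in "ACGU" if b != seq[i]]
            seq[i] = alternatives[int(rng.integers(0, 3))]
            mutated.append(i)
    return "".join(seq), mutated


def generate_hairpin_segment(stem: int, loop: int, bulges: int = 0,
                             seed: int = 0, index: int = 0) -> str:
    """A sequence of length ``2*stem + loop + bulges`` that folds with at
    least ``stem`` nested pairs (a designed hairpin, optionally with
    bulged residues on the 5' arm)."""
    if stem < 3 or loop < 3 or bulges < 0:
        raise ValueError("invalid hairpin geometry")
    rng = stream(seed, "hairpin", index)
    five, three = [], []
    for _ in range(stem):
        a, b = PAIRS[int(rng.integers(0, len(PAIRS)))]
        five.append(a)
        three.append(b)
    three.reverse()
    loop_seq = [str(BASES[int(rng.integers(0, 4))]) for _ in range(loop)]
    for _ in range(bulges):
        pos = int(rng.integers(0, len(five) + 1))
        five.insert(pos, str(BASES[int(rng.integers(0, 4))]))
    return "".join(five + loop_seq + three)


def hairpin_for_length(length: int, seed: int, index: int = 0,
                       flank5: str = "", flank3: str = "") -> str:
    """A hairpin segment of an exact total length (>= 13 nt).

    When the flanking core bases are given, the segment is regenerated (new
    substream) until its terminal bases differ from them: a segment edge
    identical to the adjacent core base makes the insertion point
    score-neutrally ambiguous for any aligner, i.e. the same molecule would
    be the truth for two different sites."""
    if length < 13:
        raise ValueError("expansion segments are at least 13 nt")
    bulges = (length - 4) % 2
    stem = (length - 4 - bulges) // 2
    for k in range(12):
        seg = generate_hairpin_segment(stem, 4, bulges, seed, index + 4096 * k)
        assert len(seg) == length
        if flank3 and seg[0] in flank3:
            continue
        if flank5 and seg[-1] in flank5:
            continue
        return seg
    return seg


class ImplantError(ValueError):
    pass


def implant_segment(gene: str, site: tuple[PositionLabel, PositionLabel],
                    segment: str,
                    schema: CoreSchema | None = None,
                    cmap: CoreAlignmentMap | None = None
                    ) -> tuple[str, int]:
    """Splice ``segment`` between the residues labelled by the ``site``
    flanks.  Position lookup uses the gene's alignment map when given,
    otherwise the schema column order (valid for substitution-only genes).

    Returns (expanded sequence, 0-based offset of the inserted run).
    Removing ``expanded[offset:offset+len(segment)]`` restores the input.
    """
    if not segment:
        raise ImplantError("cannot implant an empty segment")
    lo, hi = site
    if cmap is not None:
        index = cmap.label_index()
        if lo not in index or hi not in index:
            raise ImplantError(f"site {lo}-{hi} not present in map")
        i, j = index[lo], index[hi]
    elif schema is not None:
        if not (schema.has_label(lo) and schema.has_label(hi)):
            raise ImplantError(f"site {lo}-{hi} not present in {schema.variant} schema")
        i, j = schema.index_of(lo), schema.index_of(hi)
    else:
        raise ImplantError("need a schema or an alignment map")
    if j != i + 1:
        raise ImplantError(f"site flanks {lo}-{hi} are not adjacent")
    offset = i + 1
    return gene[:offset] + segment + gene[offset:], offset


def degrade_to_pseudogene(gene: str, drop5: int, drop3: int,
                          extra_substitutions: int = 0, seed: int = 0,
                          index: int = 0) -> str:
    """Remove terminal parts (and optionally scatter extra substitutions)."""
    if drop5 < 0 or drop3 < 0 or drop5 + drop3 >= len(gene):
        raise ValueError("over-truncation")
    remnant = list(gene[drop5: len(gene) - drop3 if drop3 else len(gene)])
    rng = stream(seed, "pseudogene", index)
    for _ in range(extra_substitutions):
        p = int(rng.integers(0, len(remnant)))
        remnant[p] = [b for b in "ACGU" if b != remnant[p]][int(rng.integers(0, 3))]
    return "".join(remnant)


# ---------------------------------------------------------------------------
# genome plans and truth
# ---------------------------------------------------------------------------

#: insertion sites offered by each schema variant (the documented site
#: inventory: loop B/helix III/loop C, the helix III bulge 52-53, loop C
#: 34-37, helix IV 3' half, and the archaeal 104.1-105 adjacent to loop E)
SITE_MENU: dict[str, tuple[str, ...]] = {
    "bacterial": ("29-30", "34-35", "36-37", "42-43", "52-53", "57-58",
                  "66-67", "89.1-90", "96-97", "105-106"),
    "archaeal": ("34-35", "57-58", "104.1-105"),
}


def parse_site(text: str) -> tuple[PositionLabel, PositionLabel]:
    a, _, b = text.partition("-")
    return (parse_position_label(a), parse_position_label(b))


@dataclass(frozen=True)
class ExpandedSpec:
    """Explicit recipe for one expanded gene."""

    variant: str
    sites: tuple[str, ...]
    lengths: tuple[int, ...]


@dataclass(frozen=True)
class GenomePlan:
    n_normal: int = 2
    n_expanded: int = 3
    n_pseudogene: int = 1
    n_chimera: int = 0
    n_tandem_dup: int = 0
    intergenic_mean: int = 300
    gc: float = 0.5
    mutation_rate: float = 0.02
    #: fraction of genes drawn from the bacterial schema (the published
    #: catalog skews bacterial: 36 bacterial vs 15 archaeal strains)
    bacterial_fraction: float = 0.7
    #: distribution of segments per molecule (1, 2, 3)
    segments_per_molecule_probs: tuple[float, ...] = (0.8, 0.15, 0.05)
    length_range: tuple[int, int] = (13, 109)
    expanded_specs: tuple[ExpandedSpec, ...] = ()

    def __post_init__(self) -> None:
        for name in ("n_normal", "n_expanded", "n_pseudogene", "n_chimera",
                     "n_tandem_dup"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class TruthImplant:
    site: str
    length: int
    offset: int      # 0-based offset of the insertion within the feature


@dataclass(frozen=True)
class TruthFeature:
    feature_id: str
    klass: str       # normal_gene | expanded_gene | pseudogene | chimera | tandem_dup
    start: int       # 0-based half-open, forward genome coordinates
    end: int
    strand: str
    variant: str
    implants: tuple[TruthImplant, ...] = ()
    parent_reference: str = ""


@dataclass(frozen=True)
class SyntheticGenome:
    genome_id: str
    sequence: str
    features: tuple[TruthFeature, ...]
    manifest: dict = field(default_factory=dict)

    def feature_sequence(self, feat: TruthFeature) -> str:
        s = self.sequence[feat.start: feat.end]
        return reverse_complement(s) if feat.strand == "-" else s


def _random_background(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=length, p=p)])


def _pick_variant(rng: np.random.Generator, plan: GenomePlan) -> str:
    return "bacterial" if rng.random() < plan.bacterial_fraction else "archaeal"


def _build_expanded(plan: GenomePlan, seed: int, index: int,
                    spec: ExpandedSpec | None
                    ) -> tuple[str, str, tuple[TruthImplant, ...], str]:
    rng = stream(seed, "expanded_layout", index)
    if spec is None:
        variant = _pick_variant(rng, plan)
        menu = SITE_MENU[variant]
        k = 1 + int(rng.choice(3, p=np.array(plan.segments_per_molecule_probs)))
        k = min(k, len(menu))
        sites = tuple(sorted(
            (menu[i] for i in rng.choice(len(menu), size=k, replace=False)),
            key=lambda s: parse_site(s)))
        lo, hi = plan.length_range
        lengths = tuple(int(rng.integers(lo, hi + 1)) for _ in sites)
    else:
        variant = spec.variant
        order = sorted(range(len(spec.sites)),
                       key=lambda i: parse_site(spec.sites[i]))
        sites = tuple(spec.sites[i] for i in order)
        lengths = tuple(spec.lengths[i] for i in order)
    schema = load_schema(variant)
    gene, _ = generate_core_gene(schema, plan.mutation_rate, seed, index)
    # keep a small window around each insertion site unmutated: mutations
    # near the junction make the placement of the inserted run ambiguous or
    # even favour a shifted placement, i.e. the implanted site would not be
    # a well-defined truth (the documented sites root in conserved
    # features such as the universally conserved helix III bulge)
    g = list(gene)
    for site in sites:
        for lab in parse_site(site):
            i = schema.index_of(lab)
            for k in range(max(0, i - 2), min(len(g), i + 3)):
                g[k] = schema.reference_sequence[k]
    gene = "".join(g)
    # implant from 3'-most to 5'-most so earlier offsets stay valid
    implants: list[TruthImplant] = []
    seq = gene
    offsets: dict[str, int] = {}
    for si in range(len(sites) - 1, -1, -1):
        lo, hi = parse_site(sites[si])
        ref = schema.reference_sequence
        segment = hairpin_for_length(
            lengths[si], seed, index * 16 + si,
            flank5=gene[schema.index_of(lo)] + ref[schema.index_of(lo)],
            flank3=gene[schema.index_of(hi)] + ref[schema.index_of(hi)])
        seq, off = implant_segment(seq, (lo, hi), segment, schema=schema)
        offsets[sites[si]] = off
        for s in list(offsets):
            if s != sites[si]:
                offsets[s] += lengths[si]
    for si, site in enumerate(sites):
        implants.append(TruthImplant(site=site, length=lengths[si],
                                     offset=offsets[site]))
    return seq, variant, tuple(implants), schema.reference_id


def generate_genome(plan: GenomePlan, seed: int, genome_id: str = "synth"
                    ) -> SyntheticGenome:
    """Assemble a genome per ``plan``; fully reproducible per seed."""
    parts: list[str] = []
    features: list[TruthFeature] = []
    cursor = 0
    layout_rng = stream(seed, "layout")
    bg_rng = stream(seed, "background")

    def _gap() -> None:
        nonlocal cursor
        length = max(50, int(layout_rng.poisson(plan.intergenic_mean)))
        parts.append(_random_background(bg_rng, length, plan.gc))
        cursor += length

    def _place(feature_id: str, klass: str, seq: str, variant: str,
               implants=(), parent: str = "") -> None:
        nonlocal cursor
        strand = "+" if layout_rng.random() < 0.5 else "-"
        emitted = reverse_complement(seq) if strand == "-" else seq
        features.append(TruthFeature(
            feature_id=feature_id, klass=klass, start=cursor,
            end=cursor + len(seq), strand=strand, variant=variant,
            implants=tuple(implants), parent_reference=parent))
        parts.append(emitted)
        cursor += len(seq)

    jobs: list[tuple[str, int]] = (
        [("normal_gene", i) for i in range(plan.n_normal)]
        + [("expanded_gene", i)
           for i in range(max(plan.n_expanded, len(plan.expanded_specs)))]
        + [("pseudogene", i) for i in range(plan.n_pseudogene)]
        + [("chimera", i) for i in range(plan.n_chimera)]
        + [("tandem_dup", i) for i in range(plan.n_tandem_dup)]
    )
    order = layout_rng.permutation(len(jobs))
    counter = 0
    for job_index in order:
        klass, i = jobs[int(job_index)]
        counter += 1
        fid = f"{genome_id}.{klass}.{i + 1}"
        _gap()
        if klass == "normal_gene":
            rng = stream(seed, "normal_variant", i)
            variant = _pick_variant(rng, plan)
            schema = load_schema(variant)
            gene, _ = generate_core_gene(schema, plan.mutation_rate,
                                         seed, 1000 + i)
            _place(fid, klass, gene, variant, parent=schema.reference_id)
        elif klass == "expanded_gene":
            spec = (plan.expanded_specs[i]
                    if i < len(plan.expanded_specs) else None)
            seq, variant, implants, parent = _build_expanded(plan, seed, i, spec)
            _place(fid, klass, seq, variant, implants, parent)
        elif klass == "pseudogene":
            # a remnant missing both termini but retaining an insertion:
            # too short to survive the >= 130 nt prefilter once detected
            rng = stream(seed, "pseudo_layout", i)
            variant = _pick_variant(rng, plan)
            schema = load_schema(variant)
            gene, _ = generate_core_gene(schema, plan.mutation_rate,
                                         seed, 2000 + i)
            menu = SITE_MENU[variant]
            # central sites only, so the 30/30-truncated remnant keeps two
            # alignable flanks and is caught (then size-rejected) downstream
            central = [s for s in menu if s in ("52-53", "57-58")] or list(menu)
            site = central[int(rng.integers(0, len(central)))]
            length = int(rng.integers(20, 36))
            lo, hi = parse_site(site)
            refseq = schema.reference_sequence
            segment = hairpin_for_length(
                length, seed, 3000 + i,
                flank5=gene[schema.index_of(lo)] + refseq[schema.index_of(lo)],
                flank3=gene[schema.index_of(hi)] + refseq[schema.index_of(hi)])
            expanded, off = implant_segment(gene, (lo, hi), segment,
                                            schema=schema)
            remnant = degrade_to_pseudogene(expanded, 35, 35)
            _place(fid, klass, remnant, variant,
                   implants=(TruthImplant(site=site, length=length,
                                          offset=off - 35),),
                   parent=schema.reference_id)
        elif klass == "chimera":
            bact, _ = generate_core_gene(load_schema("bacterial"),
                                         plan.mutation_rate, seed, 4000 + i)
            arch, _ = generate_core_gene(load_schema("archaeal"),
                                         plan.mutation_rate, seed, 5000 + i)
            _place(fid, klass, bact[:60] + arch[61:], "bacterial",
                   parent="bacterial+archaeal")
        elif klass == "tandem_dup":
            rng = stream(seed, "dup_variant", i)
            variant = _pick_variant(rng, plan)
            schema = load_schema(variant)
            gene, _ = generate_core_gene(schema, plan.mutation_rate,
                                         seed, 6000 + i)
            _place(fid, klass, gene + gene[:60], variant,
                   parent=schema.reference_id)
    _gap()
    sequence = "".join(parts)
    manifest = {
        "genome_id": genome_id, "seed": int(seed),
        "plan": {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in vars(plan).items() if k != "expanded_specs"},
        "n_features": len(features),
        "length": len(sequence),
    }
    return SyntheticGenome(genome_id=genome_id, sequence=sequence,
                           features=tuple(features), manifest=manifest)


# ---------------------------------------------------------------------------
# study-scale convenience set
# ---------------------------------------------------------------------------

def study_specs(n_expanded: int = 54) -> tuple[ExpandedSpec, ...]:
    """Deterministic expanded-gene recipes covering the documented study
    conditions: >= 10 distinct sites including the helix III bulge (52-53)
    with the 46-nt thermoanaerobacterial geometry, loop C (34-35), and the
    archaeal 104.1-105 site with the 108-nt halococcal geometry; lengths
    span the full 13-109 nt range; 1-3 segments per molecule."""
    base: list[ExpandedSpec] = [
        ExpandedSpec("bacterial", ("52-53",), (46,)),
        ExpandedSpec("archaeal", ("104.1-105",), (108,)),
        ExpandedSpec("bacterial", ("34-35",), (13,)),
        ExpandedSpec("bacterial", ("96-97",), (109,)),
        ExpandedSpec("bacterial", ("29-30", "57-58"), (21, 34)),
        ExpandedSpec("bacterial", ("36-37", "89.1-90"), (55, 17)),
        ExpandedSpec("bacterial", ("42-43", "66-67", "105-106"), (28, 40, 19)),
        ExpandedSpec("archaeal", ("34-35",), (62,)),
        ExpandedSpec("archaeal", ("57-58", "104.1-105"), (25, 73)),
        ExpandedSpec("bacterial", ("52-53",), (41,)),
    ]
    lengths = [15, 23, 31, 39, 47, 58, 67, 76, 85, 94, 103]
    sites = list(SITE_MENU["bacterial"])
    i = 0
    while len(base) < n_expanded:
        base.append(ExpandedSpec("bacterial",
                                 (sites[i % len(sites)],),
                                 (lengths[i % len(lengths)],)))
        i += 1
    return tuple(base[:n_expanded])


def generate_study_genomes(seed: int, n_genomes: int = 9,
                           specs: tuple[ExpandedSpec, ...] | None = None
                           ) -> list[SyntheticGenome]:
    """A set of genomes carrying the full study-condition spec list spread
    ~evenly, each with normal genes, a remnant, a chimera and a tandem
    duplication alongside the expanded genes."""
    specs = specs if specs is not None else study_specs()
    per = -(-len(specs) // n_genomes)
    genomes = []
    for g in range(n_genomes):
        chunk = specs[g * per: (g + 1) * per]
        plan = GenomePlan(n_normal=2, n_expanded=len(chunk), n_pseudogene=1,
                          n_chimera=1, n_tandem_dup=1,
                          expanded_specs=tuple(chunk))
        genomes.append(generate_genome(plan, seed + g,
                                       genome_id=f"synth{g + 1:02d}"))
    return genomes
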