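"""Synthetic genome generator: determinism, geometry, truth consistency."""

import numpy as np
import pytest

from xpand5s.fold import fold_max_pairing
from xpand5s.labels import parse_position_label as P
from xpand5s.synthetic import (ExpandedSpec, GenomePlan, ImplantError,
                               degrade_to_pseudogene, generate_core_gene,
                               generate_genome, generate_hairpin_segment,
                               hairpin_for_length, implant_segment,
                               study_specs)


def test_core_gene_rate_zero_is_reference(bacterial):
    seq, muts = generate_core_gene(bacterial, 0.0, seed=1)
    assert seq == bacterial.reference_sequence
    assert muts == []


def test_core_gene_deterministic(bacterial):
    a = generate_core_gene(bacterial, 0.1, seed=42)
    b = generate_core_gene(bacterial, 0.1, seed=42)
    assert a == b
    c = generate_core_gene(bacterial, 0.1, seed=43)
    assert a != c


def test_core_gene_never_touches_conserved_columns(bacterial):
    conserved = {i for i, c in enumerate(bacterial.columns) if c.conserved}
    for seed in range(20):
        _, muts = generate_core_gene(bacterial, 0.2, seed=seed)
        assert not (set(muts) & conserved)


def test_core_gene_substitution_count_binomial(bacterial):
    """Mean substitutions over seeds ~ rate x mutable columns (3 sigma)."""
    rate = 0.1
    mutable = sum(not c.conserved for c in bacterial.columns)
    counts = [len(generate_core_gene(bacterial, rate, seed=s)[1])
              for s in range(100)]
    mean = np.mean(counts)
    sigma = np.sqrt(mutable * rate * (1 - rate) / len(counts))
    assert abs(mean - rate * mutable) < 3 * sigma


def test_core_gene_rate_validation(bacterial):
    with pytest.raises(ValueError):
        generate_core_gene(bacterial, 0.5, seed=1)


# ---------------------------------------------------------------------------

@pytest.mark.parametrize("stem, loop, bulges", [(12, 4, 0), (3, 3, 0), (20, 5, 4)])
def test_hairpin_geometry(stem, loop, bulges):
    seg = generate_hairpin_segment(stem, loop, bulges, seed=9)
    assert len(seg) == 2 * stem + loop + bulges
    assert fold_max_pairing(seg).pair_count >= stem


def test_hairpin_invalid_geometry():
    with pytest.raises(ValueError):
        generate_hairpin_segment(2, 4, 0, seed=0)
    with pytest.raises(ValueError):
        hairpin_for_length(12, seed=0)


def test_hairpin_deterministic():
    assert generate_hairpin_segment(10, 4, 1, seed=5) == \
        generate_hairpin_segment(10, 4, 1, seed=5)


# ---------------------------------------------------------------------------

def test_implant_roundtrip(bacterial):
    seg = hairpin_for_length(46, seed=1)
    gene = bacterial.reference_sequence
    expanded, off = implant_segment(gene, (P("52"), P("53")), seg,
                                    schema=bacterial)
    assert len(expanded) == len(gene) + 46
    assert expanded[:off] + expanded[off + 46:] == gene
    assert expanded[off:off + 46] == seg


def test_implant_errors(bacterial, archaeal):
    seg = hairpin_for_length(20, seed=2)
    with pytest.raises(ImplantError):
        implant_segment(bacterial.reference_sequence, (P("52"), P("53")), "",
                        schema=bacterial)
    with pytest.raises(ImplantError):  # archaeal-only site on bacterial schema
        implant_segment(bacterial.reference_sequence, (P("104.1"), P("105")),
                        seg, schema=bacterial)
    with pytest.raises(ImplantError):  # non-adjacent flanks
        implant_segment(bacterial.reference_sequence, (P("52"), P("54")),
                        seg, schema=bacterial)
    # the archaeal schema does carry 104.1-105
    implant_segment(archaeal.reference_sequence, (P("104.1"), P("105")), seg,
                    schema=archaeal)


def test_pseudogene_truncation(bacterial):
    gene = bacterial.reference_sequence
    assert len(degrade_to_pseudogene(gene, 20, 0)) == len(gene) - 20
    seg = hairpin_for_length(30, seed=3)
    expanded, off = implant_segment(gene, (P("57"), P("58")), seg,
                                    schema=bacterial)
    remnant = degrade_to_pseudogene(expanded, 15, 15)
    assert seg in remnant    # the insertion survives terminal truncation
    with pytest.raises(ValueError):
        degrade_to_pseudogene(gene, len(gene), 0)


# ---------------------------------------------------------------------------

def test_featureless_plan():
    plan = GenomePlan(n_normal=0, n_expanded=0, n_pseudogene=0)
    g = generate_genome(plan, seed=3)
    assert g.features == ()
    assert len(g.sequence) >= 50


def test_plan_counts_match_truth():
    plan = GenomePlan(n_normal=3, n_expanded=2, n_pseudogene=1,
                      n_chimera=1, n_tandem_dup=1)
    g = generate_genome(plan, seed=5)
    classes = sorted(f.klass for f in g.features)
    assert classes == sorted(["normal_gene"] * 3 + ["expanded_gene"] * 2
                             + ["pseudogene", "chimera", "tandem_dup"])
    for f in g.features:
        if f.klass == "expanded_gene":
            assert len(f.implants) >= 1


def test_same_seed_is_byte_identical():
    plan = GenomePlan(n_chimera=1, n_tandem_dup=1)
    a = generate_genome(plan, seed=11)
    b = generate_genome(plan, seed=11)
    assert a.sequence == b.sequence
    assert a.features == b.features
    c = generate_genome(plan, seed=12)
    assert c.sequence != a.sequence


def test_truth_coordinates_reproduce_feature_sequences():
    """Extracting truth spans from the genome reproduces each feature's
    emitted sequence, including implant sub-spans on either strand."""
    g = generate_genome(GenomePlan(n_expanded=4), seed=21)
    for f in g.features:
        seq = g.feature_sequence(f)
        assert len(seq) == f.end - f.start
        for im in f.implants:
            assert 0 <= im.offset <= len(seq) - im.length
    strands = {f.strand for f in g.features}
    assert strands <= {"+", "-"}


def test_implant_offsets_match_truth_sites(bacterial, archaeal):
    g = generate_genome(GenomePlan(n_expanded=6, n_normal=0,
                                   n_pseudogene=0), seed=8)
    schemas = {"bacterial": bacterial, "archaeal": archaeal}
    for f in g.features:
        seq = g.feature_sequence(f)
        sch = schemas[f.variant]
        for im in sorted(f.implants, key=lambda i: i.offset):
            # removing all implants restores a pure core gene of schema size
            pass
        core_len = len(seq) - sum(im.length for im in f.implants)
        assert core_len == len(sch)


def test_study_specs_cover_required_conditions():
    specs = study_specs()
    assert len(specs) >= 50
    sites = {s for spec in specs for s in spec.sites}
    assert {"52-53", "34-35", "104.1-105"} <= sites
    assert len(sites) >= 10
    lengths = [l for spec in specs for l in spec.lengths]
    assert min(lengths) == 13 and max(lengths) == 109
    assert all(13 <= l <= 109 for l in lengths)
    assert max(len(s.sites) for s in specs) == 3
    paired = [(s.sites, s.lengths) for s in specs]
    assert (("52-53",), (46,)) in paired        # thermoanaerobacterial geometry
    assert (("104.1-105",), (108,)) in paired   # halococcal geometry
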