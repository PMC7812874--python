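"""Descriptor parsing, IUPAC predicates, and scan-vs-enumeration oracle."""

import itertools

import numpy as np
import pytest

from conftest import random_rna
from xpand5s.descriptor import (Descriptor, DescriptorError, GapBlock,
                                MotifBlock, PairConstraint, packaged_descriptor,
                                parse_descriptor, scan_descriptor)
from xpand5s.iupac import (EXPANSION, InvalidCodeError, bases_pair,
                           iupac_complementary, iupac_match, reverse_complement)

# ---------------------------------------------------------------------------
# IUPAC predicates
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("code, base, ok", [
    ("Y", "C", True), ("R", "C", False), ("N", "G", True),
    ("S", "G", True), ("S", "A", False), ("U", "T", True),
])
def test_iupac_match(code, base, ok):
    assert iupac_match(code, base) is ok


def test_iupac_match_invalid():
    with pytest.raises(InvalidCodeError):
        iupac_match("Z", "A")
    with pytest.raises(InvalidCodeError):
        iupac_match("N", "N")  # base must be concrete


def test_iupac_complementary_matches_brute_force():
    """Existential complementarity must equal brute force over the two
    code expansions, for every code pair and wobble setting."""
    for a, b in itertools.product(EXPANSION, repeat=2):
        for wobble in (False, True):
            expected = any(bases_pair(x, y, wobble)
                           for x in EXPANSION[a] for y in EXPANSION[b])
            assert iupac_complementary(a, b, wobble) == expected, (a, b, wobble)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def test_parse_single_motif():
    d = parse_descriptor("ACGU")
    assert d.blocks == (MotifBlock("ACGU"),)
    assert d.constraints == ()


def test_parse_packaged_patterns():
    thermo = packaged_descriptor("thermoanaerobacterales")
    assert [type(b).__name__ for b in thermo.blocks] == [
        "MotifBlock", "GapBlock", "MotifBlock", "GapBlock", "MotifBlock"]
    assert thermo.motifs[0].pattern == "YYYGGYGRY"
    assert thermo.motifs[1].pattern == "GAUGRUASU"
    assert thermo.motifs[2].pattern == "YYGCCRRR"
    assert thermo.blocks[1] == GapBlock(50, 180)
    assert thermo.blocks[3] == GapBlock(20, 150)
    assert len(thermo.constraints) == 1
    halo = packaged_descriptor("halobacteria")
    assert halo.motifs[0].pattern == "MGGCGGCC"
    assert halo.motifs[1].pattern == "BNNMSUACU"
    assert halo.motifs[2].pattern == "UCGCCGCC"   # T normalised to U
    # minimal and maximal spans follow from the printed pattern
    assert thermo.min_span == 9 + 9 + 8 + 50 + 20 == 96
    assert thermo.max_span == 9 + 9 + 8 + 180 + 150 == 356


@pytest.mark.parametrize("bad", [
    "N[180:50]",                      # inverted bounds
    "ACZU",                           # unknown code
    "pair(block1[0:4], block2[0:3])",  # unequal ranges (given two motifs)
])
def test_parse_errors(bad):
    text = "ACGU\nUGCA\n" + bad if bad.startswith("pair") else bad
    with pytest.raises(DescriptorError):
        parse_descriptor(text)


def test_constraint_must_reference_motif():
    with pytest.raises(DescriptorError):
        parse_descriptor("ACGU\nN[1:5]\npair(block1[0:2], block2[0:2])")


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def test_scan_constructed_positive():
    """A sequence assembled from motif matches separated by in-bound gaps
    yields a hit whose gap spans equal the construction."""
    thermo = packaged_descriptor("thermoanaerobacterales")
    m1 = "CCUGGCGGC"         # YYYGGYGRY
    m2 = "GAUGGUAGU"         # GAUGRUASU
    m3 = "CUGCCAGGC"[:8]     # YYGCCRRR -> CUGCCAGG, wobble-pairs with m1[0:8]
    seq = m1 + "A" * 60 + m2 + "A" * 30 + m3
    hits = scan_descriptor(seq, thermo)
    assert hits, "constructed positive control must match"
    h = hits[0]
    gap_spans = [h.spans[1], h.spans[3]]
    assert gap_spans[0][1] - gap_spans[0][0] == 60
    assert gap_spans[1][1] - gap_spans[1][0] == 30


def test_scan_rejects_homopolymer():
    for name in ("thermoanaerobacterales", "halobacteria"):
        d = packaged_descriptor(name)
        assert scan_descriptor("A" * 400, d) == []


def test_both_references_match_their_descriptor(bacterial, archaeal):
    thermo = packaged_descriptor("thermoanaerobacterales")
    halo = packaged_descriptor("halobacteria")
    assert scan_descriptor(bacterial.reference_sequence, thermo)
    assert scan_descriptor(archaeal.reference_sequence, halo)


# -- oracle ------------------------------------------------------------------

def enumerate_hits(seq, d):
    """Exhaustive enumeration of all satisfying placements (oracle)."""
    motifs = [(i, b) for i, b in enumerate(d.blocks) if isinstance(b, MotifBlock)]

    def match_at(pattern, p):
        if p + len(pattern) > len(seq):
            return False
        return all(seq[p + k] in EXPANSION[c] for k, c in enumerate(pattern))

    def gap_bounds(a, b):
        lo = sum(d.blocks[k].lo for k in range(a + 1, b)
                 if isinstance(d.blocks[k], GapBlock))
        hi = sum(d.blocks[k].hi for k in range(a + 1, b)
                 if isinstance(d.blocks[k], GapBlock))
        return lo, hi

    results = set()

    def rec(level, placements):
        if level == len(motifs):
            for c in d.constraints:
                pa = placements[c.block_a] + c.range_a[0]
                pb = placements[c.block_b] + c.range_b[0]
                L = c.range_a[1] - c.range_a[0]
                if not all(bases_pair(seq[pa + k], seq[pb + L - 1 - k], c.wobble)
                           for k in range(L)):
                    return
            spans = []
            cursor = None
            for i, b in enumerate(d.blocks):
                if isinstance(b, MotifBlock):
                    spans.append((placements[i], placements[i] + len(b.pattern)))
                    cursor = placements[i] + len(b.pattern)
                else:
                    nxt = min(p for j, p in placements.items() if j > i)
                    spans.append((cursor, nxt))
                    cursor = nxt
            results.add(tuple(spans))
            return
        bi, block = motifs[level]
        for p in range(len(seq) - len(block.pattern) + 1):
            if not match_at(block.pattern, p):
                continue
            if level > 0:
                pj, prev_block = motifs[level - 1]
                prev_end = placements[pj] + len(prev_block.pattern)
                lo, hi = gap_bounds(pj, bi)
                if not (prev_end + lo <= p <= prev_end + hi):
                    continue
            placements[bi] = p
            rec(level + 1, placements)
            del placements[bi]

    rec(0, {})
    return results


TOY = Descriptor(
    blocks=(MotifBlock("GGRC"), GapBlock(2, 6), MotifBlock("GYCC")),
    constraints=(PairConstraint(0, (0, 4), 2, (0, 4), wobble=False),),
)


def test_scan_equals_enumeration_on_seeded_random_sequences(rng):
    for _ in range(30):
        seq = random_rna(rng, 400)
        got = {h.spans for h in scan_descriptor(seq, TOY)}
        assert got == enumerate_hits(seq, TOY)


def test_strand_symmetry(rng):
    """Hits on the reverse complement map one-to-one to minus-strand hits
    with mirrored coordinates."""
    for _ in range(10):
        seq = random_rna(rng, 500)
        fwd_on_rc = {h.spans for h in scan_descriptor(reverse_complement(seq), TOY)}
        minus = [h for h in scan_descriptor(seq, TOY, both_strands=True)
                 if h.strand == "-"]
        n = len(seq)
        mirrored = {tuple((n - e, n - s) for (s, e) in reversed(h.spans))
                    for h in minus}
        assert mirrored == fwd_on_rc


def test_hits_sorted_and_deduplicated(rng):
    seq = random_rna(rng, 800)
    hits = scan_descriptor(seq, TOY, both_strands=True)
    starts = [h.start for h in hits]
    assert starts == sorted(starts)
    assert len({(h.strand, h.spans) for h in hits}) == len(hits)
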