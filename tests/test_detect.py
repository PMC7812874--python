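"""Split-hit detection and the validity filters."""

import pytest

from conftest import random_rna
from xpand5s.detect import (SplitParams, detect_chimera,
                            detect_internal_duplication, find_split_candidates,
                            prefilter_records)
from xpand5s.iupac import reverse_complement


def test_constructed_split_candidate(bacterial, rng):
    ref = bacterial.reference_sequence
    # insert edges differ from the junction bases so the boundary is a
    # well-defined truth rather than a score-neutral tie
    middle = random_rna(rng, 38)
    first = next(b for b in "ACGU" if b != ref[60])
    last = next(b for b in "ACGU" if b != ref[59])
    ins = first + middle + last
    genome = random_rna(rng, 200) + ref[:60] + ins + ref[60:] + random_rna(rng, 150)
    res = find_split_candidates(ref, genome)
    assert len(res.candidates) == 1
    c = res.candidates[0]
    assert c.insertion_length == 40
    assert abs(c.break_query_pos - 60) <= 2
    assert c.strand == "+"
    assert (c.insertion_start, c.insertion_end) == (260, 300)


def test_exact_copy_is_normal_match_not_candidate(bacterial, rng):
    ref = bacterial.reference_sequence
    genome = random_rna(rng, 300) + ref + random_rna(rng, 300)
    res = find_split_candidates(ref, genome)
    assert res.candidates == []
    assert len(res.normal_matches) == 1
    assert res.normal_matches[0].subject_span == (300, 420)


def test_minus_strand_candidate_reported_forward(bacterial, rng):
    ref = bacterial.reference_sequence
    ins = random_rna(rng, 25)
    gene = ref[:60] + ins + ref[60:]
    genome = random_rna(rng, 120) + reverse_complement(gene) + random_rna(rng, 90)
    res = find_split_candidates(ref, genome)
    assert len(res.candidates) == 1
    c = res.candidates[0]
    assert c.strand == "-"
    assert c.insertion_length == 25
    # forward-strand insertion span: the gene occupies [120, 120+145)
    assert (c.insertion_start, c.insertion_end) == (120 + 60, 120 + 85)


def test_monotonicity_in_parameters(bacterial, rng):
    """Widening delta_range never removes candidates; raising min_identity
    never adds any."""
    ref = bacterial.reference_sequence
    genome = (random_rna(rng, 100) + ref[:55] + random_rna(rng, 30)
              + ref[55:] + random_rna(rng, 100)
              + ref[:70] + random_rna(rng, 90) + ref[70:])
    narrow = find_split_candidates(ref, genome, SplitParams(delta_range=(10, 60)))
    wide = find_split_candidates(ref, genome, SplitParams(delta_range=(10, 250)))
    keys = lambda r: {(c.strand, c.insertion_start, c.insertion_end)
                      for c in r.candidates}
    assert keys(narrow) <= keys(wide)
    strict = find_split_candidates(ref, genome,
                                   SplitParams(min_identity=0.95))
    assert keys(strict) <= keys(wide)


# ---------------------------------------------------------------------------

def test_duplication_detected_on_constructed_repeat(rng):
    seq = random_rna(rng, 120)
    verdict = detect_internal_duplication(seq + seq[:60])
    assert verdict.duplicated
    assert verdict.identity >= 0.85


def test_duplication_clean_cases(bacterial, rng):
    assert not detect_internal_duplication(bacterial.reference_sequence).duplicated
    for _ in range(5):
        assert not detect_internal_duplication(random_rna(rng, 200)).duplicated


def test_duplication_requires_minimum_length(rng):
    with pytest.raises(ValueError):
        detect_internal_duplication("ACGU" * 10)


# ---------------------------------------------------------------------------

@pytest.fixture()
def references(bacterial, archaeal):
    return {"bact": bacterial.reference_sequence,
            "arch": archaeal.reference_sequence}


def test_chimera_detected(references):
    half_and_half = references["bact"][:60] + references["arch"][61:]
    verdict = detect_chimera(half_and_half, references)
    assert verdict.chimeric


def test_intact_reference_consistent(references):
    assert detect_chimera(references["bact"], references).status == "consistent"


def test_insertion_keeps_record_consistent(references, rng):
    seq = references["bact"][:52] + random_rna(rng, 46) + references["bact"][52:]
    assert detect_chimera(seq, references).status == "consistent"


def test_chimera_indeterminate_with_one_reference(references):
    verdict = detect_chimera(references["bact"], {"bact": references["bact"]})
    assert verdict.status == "indeterminate"


def test_shuffled_halves_on_one_reference_are_chimeric(references):
    ref = references["bact"]
    swapped = ref[60:] + ref[:60]
    assert detect_chimera(swapped, references).chimeric


# ---------------------------------------------------------------------------

def test_prefilter_rules():
    records = {
        "short": "A" * 129,
        "ambiguous": ("ACGU" * 37) + "NA",     # 150 nt with one N
        "clean": "ACGU" * 39,                   # 156 nt
        "dna_ok": "ACGT" * 40,                  # T accepted
    }
    kept, log = prefilter_records(records, min_len=130)
    assert set(kept) == {"clean", "dna_ok"}
    reasons = {r.record_id: r.reason for r in log}
    assert "length" in reasons["short"]
    assert "ambiguous" in reasons["ambiguous"].lower() or "N" in reasons["ambiguous"]
    assert len(records) == len(kept) + len(log)
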