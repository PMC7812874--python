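"""Alignment primitives against independent dynamic-programming oracles."""

import numpy as np
import pytest

from conftest import random_rna
from xpand5s.pairwise import (LOCAL_SCORING, NUMBERING_SCORING, ScoringScheme,
                              global_align, global_identity, local_align,
                              self_align_offdiagonal)

NEG = float("-inf")


def sw_score_oracle(q, s, scoring=LOCAL_SCORING):
    """Quadratic affine Smith-Waterman, score only (gap cost open + L*ext).
    Written independently of the implementation under test."""
    n, m = len(q), len(s)
    ma, mi = scoring.match, -scoring.mismatch
    go, ge = scoring.gap_open, scoring.gap_extend
    best = 0.0
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i - 1][j] - ge, H[i - 1][j] - go - ge)
            F[i][j] = max(F[i][j - 1] - ge, H[i][j - 1] - go - ge)
            diag = H[i - 1][j - 1] + (ma if q[i - 1] == s[j - 1] else mi)
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def nw_score_oracle(q, s, scoring=NUMBERING_SCORING):
    """Global affine alignment score oracle (Gotoh recurrences, scores only)."""
    n, m = len(q), len(s)
    ma, mi = scoring.match, -scoring.mismatch
    go, ge = scoring.gap_open, scoring.gap_extend
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(go + ge * i)
    for j in range(1, m + 1):
        Y[0][j] = -(go + ge * j)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = ma if q[i - 1] == s[j - 1] else mi
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + sub
            X[i][j] = max(M[i - 1][j] - go - ge, Y[i - 1][j] - go - ge,
                          X[i - 1][j] - ge)
            Y[i][j] = max(M[i][j - 1] - go - ge, X[i][j - 1] - go - ge,
                          Y[i][j - 1] - ge)
    return max(M[n][m], X[n][m], Y[n][m])


# ---------------------------------------------------------------------------

def test_identical_sequences_full_hit():
    seq = "ACGU" * 30
    hits = local_align(seq, seq)
    assert hits[0].score == len(seq) * LOCAL_SCORING.match
    assert hits[0].query_span == (0, len(seq))
    assert hits[0].subject_span == (0, len(seq))
    assert hits[0].identity == 1.0


def test_embedded_copy_is_top_hit(rng):
    query = random_rna(rng, 80)
    subject = random_rna(rng, 500) + query + random_rna(rng, 420)
    top = local_align(query, subject)[0]
    assert top.subject_span == (500, 580)
    assert top.query_span == (0, 80)


def test_local_scores_match_brute_force_oracle(rng):
    """Exact affine SW scores equal an independent quadratic DP on seeded
    random instances (planted partial similarity included)."""
    for k in range(60):
        q = random_rna(rng, int(rng.integers(20, 50)))
        s = random_rna(rng, int(rng.integers(60, 200)))
        if k % 2:  # plant a degraded copy so scores are non-trivial
            pos = int(rng.integers(0, len(s) - len(q)))
            degraded = list(q)
            for _ in range(4):
                p = int(rng.integers(0, len(q)))
                degraded[p] = "ACGU"[int(rng.integers(0, 4))]
            s = s[:pos] + "".join(degraded) + s[pos + len(q):]
        expected = sw_score_oracle(q, s)
        hits = local_align(q, s, min_score=1.0, max_hits=1)
        got = hits[0].score if hits else 0.0
        assert got == pytest.approx(expected), (q, s)


def test_suboptimal_hits_do_not_overlap_on_subject(rng):
    q = random_rna(rng, 60)
    s = q + random_rna(rng, 100) + q + random_rna(rng, 100) + q
    hits = local_align(q, s, max_hits=5)
    assert len(hits) >= 3
    spans = sorted(h.subject_span for h in hits)
    assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))


# ---------------------------------------------------------------------------

def test_global_align_score_matches_oracle(rng):
    for _ in range(40):
        q = random_rna(rng, int(rng.integers(5, 60)))
        r = random_rna(rng, int(rng.integers(5, 60)))
        score, path = global_align(q, r)
        assert score == pytest.approx(nw_score_oracle(q, r))
        # the path covers both sequences exactly once
        q_idx = [qi for op, qi, rj in path if qi >= 0]
        r_idx = [rj for op, qi, rj in path if rj >= 0]
        assert q_idx == list(range(len(q)))
        assert r_idx == list(range(len(r)))


def test_global_identity_bounds_and_self():
    assert global_identity("ACGUACGU", "ACGUACGU") == 1.0
    assert 0.0 <= global_identity("ACGUACGU", "UUUU") <= 1.0
    assert global_identity("", "ACGU") == 0.0


# ---------------------------------------------------------------------------

def test_self_align_finds_planted_duplication(rng):
    core = random_rna(rng, 120)
    seq = core + core[:60]
    hit = self_align_offdiagonal(seq, min_offset=40)
    assert hit is not None
    assert hit.identity > 0.95
    assert min(hit.query_end - hit.query_start,
               hit.subject_end - hit.subject_start) >= 55


def test_self_align_clean_on_random(rng):
    """Random sequences must not show long high-identity off-diagonal
    self-hits (cross-checked length bound, not just score)."""
    for _ in range(10):
        seq = random_rna(rng, 200)
        hit = self_align_offdiagonal(seq, min_offset=40)
        if hit is not None:
            length = min(hit.query_end - hit.query_start,
                         hit.subject_end - hit.subject_start)
            assert length < 40 or hit.identity < 0.85


def test_scoring_scheme_validation():
    with pytest.raises(ValueError):
        ScoringScheme(match=0)
    with pytest.raises(ValueError):
        ScoringScheme(mismatch=-1)
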