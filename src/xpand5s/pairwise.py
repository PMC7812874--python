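"""Pairwise alignment primitives.

Three tools live here:

* :func:`global_align` — an affine-gap Needleman-Wunsch/Gotoh aligner with a
  deterministic traceback, used for numbering query residues against a core
  schema and for identity computations.  Pure Python; the sequences it sees
  are short (a 5S gene against a ~120-column core).
* :func:`local_align` — affine-gap Smith-Waterman local search with
  extraction of suboptimal hits, backed by Bio.Align.PairwiseAligner (exact
  dynamic programming in C) with recursive re-search of the subject flanks,
  so reported hits never overlap on the subject.
* :func:`self_align_offdiagonal` — Smith-Waterman of a sequence against
  itself with the near-diagonal band forbidden, the primitive behind
  internal-duplication detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .iupac import normalize


@dataclass(frozen=True)
class ScoringScheme:
    """Affine scoring; gap of length L costs ``gap_open + L * gap_extend``."""

    match: float = 2.0
    mismatch: float = 3.0   # penalty (subtracted)
    gap_open: float = 5.0   # penalty
    gap_extend: float = 2.0  # penalty

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if min(self.mismatch, self.gap_open, self.gap_extend) < 0:
            raise ValueError("penalties must be non-negative")


#: default scoring for local genome screens (BLASTN-like +2/-3, gap 5+2L)
LOCAL_SCORING = ScoringScheme(match=2, mismatch=3, gap_open=5, gap_extend=2)
#: default scoring for core numbering (+2/-1, gap 6+1L)
NUMBERING_SCORING = ScoringScheme(match=2, mismatch=1, gap_open=6, gap_extend=1)


@dataclass(frozen=True)
class LocalHit:
    """A local alignment hit; spans are 0-based half-open."""

    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    strand: str
    score: float
    identity: float
    blocks: tuple[tuple[int, int, int, int], ...] = field(default=())

    @property
    def query_span(self) -> tuple[int, int]:
        return (self.query_start, self.query_end)

    @property
    def subject_span(self) -> tuple[int, int]:
        return (self.subject_start, self.subject_end)

    @property
    def length(self) -> int:
        return self.query_end - self.query_start


# ---------------------------------------------------------------------------
# global affine alignment (Gotoh), deterministic traceback
# ---------------------------------------------------------------------------

NEG = float("-inf")


def global_align(query: str, ref: str,
                 scoring: ScoringScheme = NUMBERING_SCORING
                 ) -> tuple[float, list[tuple[str, int, int]]]:
    """Globally align ``query`` to ``ref`` with affine gaps.

    Returns ``(score, path)`` where path is a list of columns:
    ``("M", qi, rj)`` residue qi aligned to reference column rj,
    ``("I", qi, -1)`` query-only column (insertion relative to the reference),
    ``("D", -1, rj)`` reference-only column (deletion).
    Ties are broken M > I > D during the backward traceback, which places
    ambiguous insertion runs as early (5'-ward) as scores permit.
    """
    q, r = normalize(query), normalize(ref)
    n, m = len(q), len(r)
    ma, mi = scoring.match, -scoring.mismatch
    go, ge = scoring.gap_open, scoring.gap_extend

    # M[i][j]: best ending in aligned pair; X: gap in ref (query-only);
    # Y: gap in query (ref-only).  Row-rolling keeps memory linear but we
    # need full traceback, so store compact direction codes instead.
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(go + ge * i)
    for j in range(1, m + 1):
        Y[0][j] = -(go + ge * j)
    for i in range(1, n + 1):
        qi = q[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, m + 1):
            s = ma if qi == r[j - 1] else mi
            Mi[j] = max(Mp[j - 1], Xp[j - 1], Yp[j - 1]) + s
            Xi[j] = max(max(Mp[j], Yp[j]) - go - ge, Xp[j] - ge)
            Yi[j] = max(max(Mi[j - 1], Xi[j - 1]) - go - ge, Yi[j - 1] - ge)

    score = max(M[n][m], X[n][m], Y[n][m])
    # backward traceback
    path: list[tuple[str, int, int]] = []
    i, j = n, m
    state = max((("M", M[n][m]), ("I", X[n][m]), ("D", Y[n][m])),
                key=lambda t: t[1])[0]
    while i > 0 or j > 0:
        if state == "M":
            path.append(("M", i - 1, j - 1))
            prev = max((("M", M[i - 1][j - 1]), ("I", X[i - 1][j - 1]),
                        ("D", Y[i - 1][j - 1])), key=lambda t: t[1])[0]
            i, j = i - 1, j - 1
            state = prev if (i > 0 or j > 0) else "M"
            if i == 0 and j == 0:
                break
        elif state == "I":
            path.append(("I", i - 1, -1))
            # did this gap open here?
            opened = max(M[i - 1][j], Y[i - 1][j]) - go - ge
            extended = X[i - 1][j] - ge
            if opened >= extended:
                state = "M" if M[i - 1][j] >= Y[i - 1][j] else "D"
            i -= 1
        else:  # "D"
            path.append(("D", -1, j - 1))
            opened = max(M[i][j - 1], X[i][j - 1]) - go - ge
            extended = Y[i][j - 1] - ge
            if opened >= extended:
                state = "M" if M[i][j - 1] >= X[i][j - 1] else "I"
            j -= 1
        if i == 0 and j == 0:
            break
    path.reverse()
    return score, path


def global_identity(a: str, b: str, denominator: str = "shorter",
                    scoring: ScoringScheme = NUMBERING_SCORING) -> float:
    """Fraction of identical aligned residues under a global alignment.

    ``denominator`` is ``"shorter"`` (matches / min(len a, len b)) or
    ``"columns"`` (matches / alignment columns including gaps).
    """
    a, b = normalize(a), normalize(b)
    if not a or not b:
        return 0.0
    _, path = global_align(a, b, scoring)
    matches = sum(1 for op, qi, rj in path if op == "M" and a[qi] == b[rj])
    if denominator == "shorter":
        return matches / min(len(a), len(b))
    if denominator == "columns":
        return matches / len(path)
    raise ValueError(f"unknown denominator {denominator!r}")


# ---------------------------------------------------------------------------
# local alignment (Smith-Waterman via Biopython) with suboptimal hits
# ---------------------------------------------------------------------------

def _make_aligner(scoring: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring.match
    aligner.mismatch_score = -scoring.mismatch
    # Biopython charges open_gap_score for the first gapped column:
    # a length-L gap costs open + (L-1)*extend, so fold one extend into open.
    aligner.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def _one_local_hit(aligner, query: str, subject: str) -> LocalHit | None:
    if not query or not subject:
        return None
    alignments = aligner.align(query, subject)
    try:
        aln = alignments[0]
    except IndexError:
        return None
    if aln.score <= 0:
        return None
    qblocks, sblocks = aln.aligned
    if len(qblocks) == 0:
        return None
    blocks = tuple(
        (int(qb[0]), int(qb[1]), int(sb[0]), int(sb[1]))
        for qb, sb in zip(qblocks, sblocks)
    )
    matches = sum(
        1
        for (q0, q1, s0, s1) in blocks
        for k in range(q1 - q0)
        if query[q0 + k] == subject[s0 + k]
    )
    q0, q1 = blocks[0][0], blocks[-1][1]
    s0, s1 = blocks[0][2], blocks[-1][3]
    columns = sum(b[1] - b[0] for b in blocks)
    # add internal gap columns
    for (a, b) in zip(blocks, blocks[1:]):
        columns += (b[0] - a[1]) + (b[2] - a[3])
    return LocalHit(q0, q1, s0, s1, "+", float(aln.score),
                    matches / columns if columns else 0.0, blocks)


def local_align(query: str, subject: str,
                scoring: ScoringScheme = LOCAL_SCORING,
                max_hits: int = 10, min_score: float = 20.0) -> list[LocalHit]:
    """Exact affine local alignment with suboptimal-hit extraction.

    The best hit is reported first; the subject flanks on either side of it
    are then re-searched recursively (up to ``max_hits`` hits with score >=
    ``min_score``), so hits never overlap on the subject.
    """
    query, subject = normalize(query), normalize(subject)
    aligner = _make_aligner(scoring)
    hits: list[LocalHit] = []
    jobs = [(0, subject)]
    while jobs and len(hits) < max_hits:
        offset, frag = jobs.pop()
        hit = _one_local_hit(aligner, query, frag)
        if hit is None or hit.score < min_score:
            continue
        shifted = LocalHit(
            hit.query_start, hit.query_end,
            hit.subject_start + offset, hit.subject_end + offset,
            "+", hit.score, hit.identity,
            tuple((q0, q1, s0 + offset, s1 + offset)
                  for (q0, q1, s0, s1) in hit.blocks),
        )
        hits.append(shifted)
        jobs.append((offset, frag[: hit.subject_start]))
        jobs.append((offset + hit.subject_end, frag[hit.subject_end:]))
    hits.sort(key=lambda h: (-h.score, h.subject_start, h.query_start))
    return hits


# ---------------------------------------------------------------------------
# off-diagonal self-alignment (duplication detection primitive)
# ---------------------------------------------------------------------------

def self_align_offdiagonal(seq: str, min_offset: int = 40,
                           scoring: ScoringScheme = LOCAL_SCORING
                           ) -> LocalHit | None:
    """Best local alignment of ``seq`` against itself with cells closer than
    ``min_offset`` to the main diagonal forbidden (the trivial self-match and
    short-period repeats are excluded).  Returns the best off-diagonal hit
    with i < j, or None when nothing scores above zero."""
    s = normalize(seq)
    n = len(s)
    if n < 4:
        return None
    ma, mi = scoring.match, -scoring.mismatch
    go, ge = scoring.gap_open, scoring.gap_extend
    best = (0.0, -1, -1, (0, 0))
    # H/E/F per Gotoh, restricted to j - i >= min_offset (upper triangle);
    # each state carries the (i, j) cell where its alignment started.
    H = [0.0] * (n + 1)
    E = [NEG] * (n + 1)  # gap on the i-axis (vertical)
    sH: list[tuple[int, int]] = [(0, j) for j in range(n + 1)]
    sE: list[tuple[int, int]] = [(0, 0)] * (n + 1)
    for i in range(1, n + 1):
        Hp, sHp = H[:], sH[:]
        F, sF = NEG, (0, 0)
        H[0] = 0.0
        sH[0] = (i, 0)
        ci = s[i - 1]
        for j in range(1, n + 1):
            if j - i < min_offset:
                H[j], E[j] = 0.0, NEG
                sH[j] = (i, j)
                continue
            diag = Hp[j - 1] + (ma if ci == s[j - 1] else mi)
            if E[j] - ge >= Hp[j] - go - ge:
                E[j] = E[j] - ge
            else:
                E[j], sE[j] = Hp[j] - go - ge, sHp[j]
            if F - ge >= H[j - 1] - go - ge:
                F = F - ge
            else:
                F, sF = H[j - 1] - go - ge, sH[j - 1]
            h = max(0.0, diag, E[j], F)
            if h == 0.0:
                sH[j] = (i, j)
            elif h == diag:
                sH[j] = sHp[j - 1]
            elif h == E[j]:
                sH[j] = sE[j]
            else:
                sH[j] = sF
            H[j] = h
            if h > best[0]:
                best = (h, i, j, sH[j])
    score, bi, bj, (si, sj) = best
    if score <= 0:
        return None
    # spans: first region on i-axis, second on j-axis (i < j by construction)
    a0, a1, b0, b1 = si, bi, sj, bj
    ident = global_identity(s[a0:a1], s[b0:b1], denominator="columns")
    return LocalHit(a0, a1, b0, b1, "+", score, ident)
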