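"""Split-hit detection of expanded 5S genes and validity filters.

The genomic screen looks for cases where the 5' and 3' parts of a normal 5S
rRNA query make separate high-scoring local hits to a genome at a distance
compatible with an intervening insertion.  Because the exact affine
Smith-Waterman optimum bridges a 13-109 nt insertion as a single internal
gap (unlike a heuristic X-dropoff search, which terminates extension), the
optimal hit is additionally decomposed at large subject-side gaps before
pairing, recovering the same split-hit signature with exact arithmetic.

Validity filters mirror the published screen: minimum record size, a strict
no-ambiguity rule, internal-duplication exclusion via off-diagonal
self-alignment, and chimera exclusion via half-sequence best-hit
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .iupac import normalize, reverse_complement
from .pairwise import (LOCAL_SCORING, LocalHit, ScoringScheme, global_identity,
                       local_align, self_align_offdiagonal)


@dataclass(frozen=True)
class SplitParams:
    # the flank downstream of the 3'-most documented insertion sites
    # (104.1-105, 105-106) is only 15-17 nt and local alignment may trim a
    # mutated terminal base or two, so the half-hit length floor sits well
    # below the desk-scale default; the score and identity floors still
    # exclude spurious short hits
    min_hit_len: int = 12
    min_identity: float = 0.7
    delta_range: tuple[int, int] = (10, 250)
    max_query_overlap: int = 5
    # the query is contiguous across a genuine insertion point, so the two
    # half-hits may leave only a few unaligned query bases between them;
    # this also prevents pairing hits that skip over a third hit
    max_query_gap: int = 10
    # hit budget per (reference, strand): a genome region with many 5S loci
    # yields several high-scoring hits per locus, so the suboptimal-hit
    # budget must exceed the default desk-scale K
    max_hits: int = 80
    min_score: float = 20.0
    scoring: ScoringScheme = field(default_factory=lambda: LOCAL_SCORING)


@dataclass(frozen=True)
class SplitCandidate:
    """A colinear 5'/3' hit pair diagnostic of an insertion."""

    reference_id: str
    genome_id: str
    strand: str
    five_prime: LocalHit
    three_prime: LocalHit
    insertion_start: int     # subject coordinates, 0-based half-open,
    insertion_end: int       # forward strand of the genome
    insertion_length: int    # subject gap minus query gap
    break_query_pos: int     # query coordinate of the inferred break
    gene_start: int          # full inferred gene span on the genome
    gene_end: int


@dataclass(frozen=True)
class DetectionResult:
    candidates: list[SplitCandidate]
    normal_matches: list[LocalHit]   # full-length single hits, delta ~ 0
    partial_hits: list[LocalHit]     # everything else above threshold


# ---------------------------------------------------------------------------
# hit decomposition and pairing
# ---------------------------------------------------------------------------

def _decompose_at_subject_gaps(hit: LocalHit, min_gap: int) -> list[LocalHit]:
    """Split a gapped hit into sub-hits at subject-only gaps >= min_gap."""
    if not hit.blocks:
        return [hit]
    groups: list[list[tuple[int, int, int, int]]] = [[hit.blocks[0]]]
    for prev, cur in zip(hit.blocks, hit.blocks[1:]):
        subject_gap = cur[2] - prev[3]
        query_gap = cur[0] - prev[1]
        if subject_gap - query_gap >= min_gap:
            groups.append([cur])
        else:
            groups[-1].append(cur)
    if len(groups) == 1:
        return [hit]
    out = []
    for g in groups:
        q0, q1, s0, s1 = g[0][0], g[-1][1], g[0][2], g[-1][3]
        out.append(LocalHit(q0, q1, s0, s1, hit.strand, hit.score,
                            hit.identity, tuple(g)))
    return out


def _trim_hit(hit: LocalHit, qmin: int | None = None, qmax: int | None = None
              ) -> LocalHit | None:
    """Restrict a hit to query coordinates [qmin, qmax); None when empty."""
    blocks = []
    for (q0, q1, s0, s1) in hit.blocks:
        if qmin is not None and q1 <= qmin:
            continue
        if qmax is not None and q0 >= qmax:
            continue
        a0, a1 = q0, q1
        b0, b1 = s0, s1
        if qmin is not None and q0 < qmin:
            b0 += qmin - q0
            a0 = qmin
        if qmax is not None and q1 > qmax:
            b1 -= q1 - qmax
            a1 = qmax
        blocks.append((a0, a1, b0, b1))
    if not blocks:
        return None
    return LocalHit(blocks[0][0], blocks[-1][1], blocks[0][2], blocks[-1][3],
                    hit.strand, hit.score, hit.identity, tuple(blocks))


def _overlap_identity(hit: LocalHit, lo: int, hi: int,
                      query: str, subject: str) -> float:
    """Match fraction of a hit restricted to query range [lo, hi)."""
    sub = _trim_hit(hit, qmin=lo, qmax=hi)
    if sub is None:
        return 0.0
    return _subhit_identity(sub, query, subject)


def _reconcile_overlap(h5: LocalHit, h3: LocalHit, query: str, subject: str,
                       params: "SplitParams") -> tuple[LocalHit, LocalHit] | None:
    """Resolve a query overlap beyond the tolerated micro-homology by
    trimming the hit whose overlapping stretch aligns worse (a local hit
    can over-extend across an insertion boundary by chance similarity);
    ties trim the 5' hit."""
    v = h5.query_end - h3.query_start
    if v <= params.max_query_overlap:
        return h5, h3
    if v > 45:
        return None
    lo, hi = h3.query_start, h5.query_end
    id5 = _overlap_identity(h5, lo, hi, query, subject)
    id3 = _overlap_identity(h3, lo, hi, query, subject)
    if id3 < id5:
        h3t = _trim_hit(h3, qmin=hi)
        if h3t is None:
            return None
        return h5, h3t
    h5t = _trim_hit(h5, qmax=lo)
    if h5t is None:
        return None
    return h5t, h3


def _subhit_identity(hit: LocalHit, query: str, subject: str) -> float:
    matches = cols = 0
    for (q0, q1, s0, s1) in hit.blocks:
        for k in range(q1 - q0):
            cols += 1
            if query[q0 + k] == subject[s0 + k]:
                matches += 1
    for a, b in zip(hit.blocks, hit.blocks[1:]):
        cols += (b[0] - a[1]) + (b[2] - a[3])
    return matches / cols if cols else 0.0


def find_split_candidates(reference: str, genome: str,
                          params: SplitParams | None = None,
                          reference_id: str = "ref",
                          genome_id: str = "genome") -> DetectionResult:
    """Screen ``genome`` (both strands) for split hits of ``reference``.

    ``reference`` should be a normal-length 5S sequence (~90-135 nt).
    Candidates are reported in forward-strand genome coordinates; full-length
    single hits are returned separately as normal-gene matches.
    """
    params = params or SplitParams()
    ref = normalize(reference)
    if not (60 <= len(ref) <= 200):
        raise ValueError("reference must be a plausible single 5S sequence")
    candidates: list[SplitCandidate] = []
    normals: list[LocalHit] = []
    partials: list[LocalHit] = []
    fwd = normalize(genome)
    glen = len(fwd)
    for strand, subject in (("+", fwd), ("-", reverse_complement(fwd))):
        raw_hits = local_align(ref, subject, params.scoring,
                               max_hits=params.max_hits,
                               min_score=params.min_score)
        subhits: list[LocalHit] = []
        for h in raw_hits:
            for sh in _decompose_at_subject_gaps(h, params.delta_range[0]):
                sh = replace(sh, strand=strand,
                             identity=_subhit_identity(sh, ref, subject))
                subhits.append(sh)
        subhits = [h for h in subhits
                   if h.length >= params.min_hit_len
                   and h.identity >= params.min_identity]
        subhits.sort(key=lambda h: (h.query_start, h.subject_start))
        used_in_pair: set[int] = set()
        for i, h5 in enumerate(subhits):
            for j, h3 in enumerate(subhits):
                if i == j:
                    continue
                if (h5.query_start >= h3.query_start
                        or h5.subject_start >= h3.subject_start):
                    continue
                pair = _reconcile_overlap(h5, h3, ref, subject, params)
                if pair is None:
                    continue
                p5, p3 = pair
                if min(p5.length, p3.length) < params.min_hit_len:
                    continue
                cand = _pair_hits(p5, p3, params)
                if cand is None:
                    continue
                delta, brk = cand
                ins_s = p5.subject_end
                ins_e = p3.subject_start
                # extend the hit span by at most a few unaligned query-tail
                # bases: restores trimmed gene termini without pulling long
                # flanking background into remnant-derived candidates
                gene_s = p5.subject_start - min(p5.query_start, 5)
                gene_e = p3.subject_end + min(len(ref) - p3.query_end, 5)
                gene_s, gene_e = max(0, gene_s), min(len(subject), gene_e)
                if strand == "-":
                    ins_s, ins_e = glen - ins_e, glen - ins_s
                    gene_s, gene_e = glen - gene_e, glen - gene_s
                candidates.append(SplitCandidate(
                    reference_id=reference_id, genome_id=genome_id,
                    strand=strand, five_prime=p5, three_prime=p3,
                    insertion_start=ins_s, insertion_end=ins_e,
                    insertion_length=delta, break_query_pos=brk,
                    gene_start=gene_s, gene_end=gene_e))
                used_in_pair.update((i, j))
        for i, h in enumerate(subhits):
            if i in used_in_pair:
                continue
            h_fwd = h
            if strand == "-":
                h_fwd = replace(h, subject_start=glen - h.subject_end,
                                subject_end=glen - h.subject_start)
            # a normal-gene match must cover the reference end to end at
            # near-reference identity; anything weaker stays a partial hit
            # (a chimeric locus can yield a full-coverage but low-identity
            # alignment bridging its foreign half)
            if (h.query_start <= 5 and h.query_end >= len(ref) - 5
                    and h.identity >= 0.9):
                normals.append(h_fwd)
            else:
                partials.append(h_fwd)
    candidates.sort(key=lambda c: (c.genome_id, c.insertion_start, c.strand))
    return DetectionResult(candidates=candidates, normal_matches=normals,
                           partial_hits=partials)


def _pair_hits(h5: LocalHit, h3: LocalHit, params: SplitParams
               ) -> tuple[int, int] | None:
    """Return (insertion length, break position) when h5/h3 form a valid
    colinear split pair, else None."""
    if h5.query_start >= h3.query_start or h5.subject_start >= h3.subject_start:
        return None
    query_gap = h3.query_start - h5.query_end      # may be slightly negative
    if not (-params.max_query_overlap <= query_gap <= params.max_query_gap):
        return None
    subject_gap = h3.subject_start - h5.subject_end
    if subject_gap < 0:
        return None
    delta = subject_gap - query_gap
    if not (params.delta_range[0] <= delta <= params.delta_range[1]):
        return None
    if query_gap >= 0:
        brk = h5.query_end
    else:  # overlap: midpoint, ties toward 5'
        brk = (h5.query_end + h3.query_start) // 2
    return delta, brk


# ---------------------------------------------------------------------------
# validity filters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DuplicationVerdict:
    duplicated: bool
    regions: tuple[tuple[int, int], tuple[int, int]] | None = None
    identity: float = 0.0


def detect_internal_duplication(seq: str, min_len: int = 40,
                                min_identity: float = 0.85) -> DuplicationVerdict:
    """Flag a record whose sequence aligns to itself off the main diagonal
    over >= ``min_len`` nt at >= ``min_identity`` identity."""
    s = normalize(seq)
    if len(s) < 60:
        raise ValueError("sequence too short for duplication screen")
    hit = self_align_offdiagonal(s, min_offset=min_len)
    if hit is None:
        return DuplicationVerdict(False)
    length = min(hit.query_end - hit.query_start,
                 hit.subject_end - hit.subject_start)
    if length >= min_len and hit.identity >= min_identity:
        return DuplicationVerdict(True,
                                  regions=((hit.query_start, hit.query_end),
                                           (hit.subject_start, hit.subject_end)),
                                  identity=hit.identity)
    return DuplicationVerdict(False)


@dataclass(frozen=True)
class ChimeraVerdict:
    status: str                      # "consistent" | "chimeric" | "indeterminate"
    details: str = ""

    @property
    def chimeric(self) -> bool:
        return self.status == "chimeric"


def detect_chimera(seq: str, references: dict[str, str],
                   identity_threshold: float = 0.8,
                   scoring: ScoringScheme = LOCAL_SCORING) -> ChimeraVerdict:
    """Compare best hits of the 5' and 3' halves against a reference set.

    Chimeric when the halves hit references less than ``identity_threshold``
    identical to each other, or colinearity-incompatible coordinates on a
    single reference."""
    s = normalize(seq)
    if len(references) < 2:
        return ChimeraVerdict("indeterminate", "need at least 2 references")
    mid = len(s) // 2
    halves = (s[:mid], s[mid:])
    best: list[tuple[str, LocalHit] | None] = [None, None]
    for hi, half in enumerate(halves):
        top_score = 0.0
        for rid, rseq in sorted(references.items()):
            hits = local_align(half, rseq, scoring, max_hits=1)
            if hits and hits[0].score > top_score:
                top_score = hits[0].score
                best[hi] = (rid, hits[0])
    if best[0] is None or best[1] is None:
        return ChimeraVerdict("indeterminate", "a half has no reference hit")
    (rid5, hit5), (rid3, hit3) = best
    if rid5 != rid3:
        ident = global_identity(references[rid5], references[rid3],
                                denominator="shorter")
        if ident < identity_threshold:
            return ChimeraVerdict(
                "chimeric",
                f"5' half hits {rid5}, 3' half hits {rid3} "
                f"(reference identity {ident:.2f})")
        return ChimeraVerdict("consistent",
                              f"halves hit near-identical references "
                              f"{rid5}/{rid3}")
    # same reference: flag only a truly reversed arrangement (the 3' half
    # landing wholly upstream of the 5' half); moderate overlap is expected
    # because a local hit can over-extend past the record midpoint
    if hit3.subject_end <= hit5.subject_start + 10:
        return ChimeraVerdict("chimeric",
                              f"halves hit {rid5} in incompatible order")
    return ChimeraVerdict("consistent", f"both halves hit {rid5} colinearly")


@dataclass(frozen=True)
class Rejection:
    record_id: str
    reason: str


def prefilter_records(records: dict[str, str], min_len: int = 130,
                      forbid_ambiguous: bool = True
                      ) -> tuple[dict[str, str], list[Rejection]]:
    """Size and ambiguity screen: keep records of length >= ``min_len``
    composed purely of A/C/G/U(T)."""
    kept: dict[str, str] = {}
    log: list[Rejection] = []
    for rid, seq in records.items():
        s = normalize(seq)
        if len(s) < min_len:
            log.append(Rejection(rid, f"length {len(s)} < {min_len}"))
            continue
        if forbid_ambiguous and (set(s) - set("ACGU")):
            bad = "".join(sorted(set(s) - set("ACGU")))
            log.append(Rejection(rid, f"ambiguous nucleotides ({bad})"))
            continue
        kept[rid] = s
    return kept, log
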