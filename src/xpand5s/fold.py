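"""Nested base-pair maximisation folding and segment-independence scores.

Expansion segments are expected to fold as self-contained helical modules:
extensive internal base-pairing, and no noticeable complementarity to the
core sequence.  The shipped criterion is base-pair maximisation (Nussinov
dynamic programming) rather than free-energy minimisation — fully
reproducible with no thermodynamic tables.  An optional hook
(:func:`fold_external`) shells out to RNAfold for comparison and is not
part of the core criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

from .iupac import bases_pair, normalize


@dataclass(frozen=True)
class FoldResult:
    sequence: str
    pairing: tuple[tuple[int, int], ...]   # (i, j) 0-based, i < j, nested
    dot_bracket: str

    @property
    def pair_count(self) -> int:
        return len(self.pairing)

    @property
    def internal_fraction(self) -> float:
        """Fraction of residues involved in a pair: 2*pairs/length."""
        if not self.sequence:
            return 0.0
        return 2.0 * len(self.pairing) / len(self.sequence)


def fold_max_pairing(seq: str, min_loop: int = 3, wobble: bool = True) -> FoldResult:
    """Maximum number of nested Watson-Crick (+wobble) pairs with hairpin
    loops of at least ``min_loop`` unpaired residues.

    Traceback is deterministic: when closing an interval, pairing the 3'
    residue with its smallest admissible partner is preferred over leaving
    it unpaired whenever the pair attains the maximum.
    """
    s = normalize(seq)
    n = len(s)
    if n == 0:
        raise ValueError("empty sequence")
    # M[i][j] over half-open logic: interval [i, j] inclusive
    M = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = M[i][j - 1]  # j unpaired
            for k in range(i, j - min_loop):
                if bases_pair(s[k], s[j], wobble):
                    left = M[i][k - 1] if k > i else 0
                    inner = M[k + 1][j - 1] if k + 1 <= j - 1 else 0
                    cand = left + 1 + inner
                    if cand > best:
                        best = cand
            M[i][j] = best

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= min_loop:
            continue
        target = M[i][j]
        chosen = None
        for k in range(i, j - min_loop):
            if bases_pair(s[k], s[j], wobble):
                left = M[i][k - 1] if k > i else 0
                inner = M[k + 1][j - 1] if k + 1 <= j - 1 else 0
                if left + 1 + inner == target:
                    chosen = k
                    break  # smallest partner k on ties
        if chosen is not None:  # prefer pairing j over leaving it unpaired
            k = chosen
            pairs.append((k, j))
            if k > i:
                stack.append((i, k - 1))
            if k + 1 <= j - 1:
                stack.append((k + 1, j - 1))
        else:
            stack.append((i, j - 1))

    pairs.sort()
    db = ["."] * n
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    return FoldResult(sequence=s, pairing=tuple(pairs), dot_bracket="".join(db))


def segment_independence(segment: str, core: str, min_loop: int = 3,
                         wobble: bool = True) -> tuple[float, int]:
    """Scores for a candidate expansion segment against its host core.

    Returns ``(internal_fraction, max_cross_complement_run)``: the folded
    internal pairing fraction of the segment, and the length of the longest
    run of consecutive segment bases exactly reverse-complementary (with
    optional wobble) to a run in the core.
    """
    seg, cor = normalize(segment), normalize(core)
    if not seg or not cor:
        raise ValueError("segment and core must be non-empty")
    internal = fold_max_pairing(seg, min_loop=min_loop, wobble=wobble).internal_fraction
    # L[i][j]: length of complementary run ending at seg[i] paired with
    # core[j]; antiparallel, so the previous element is (i-1, j+1).
    n, m = len(seg), len(cor)
    best = 0
    prev = [0] * (m + 1)
    for i in range(n):
        cur = [0] * (m + 1)
        for j in range(m - 1, -1, -1):
            if bases_pair(seg[i], cor[j], wobble):
                cur[j] = prev[j + 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return internal, best


def fold_external(seq: str):  # pragma: no cover - optional comparison hook
    """Non-core hook: fold with RNAfold if ViennaRNA is on PATH.

    Returns the (dot_bracket, mfe) pair or None when the tool is missing.
    Provided for manual comparison with the shipped pair-maximisation
    criterion; nothing in the package depends on it.
    """
    import shutil
    import subprocess

    if shutil.which("RNAfold") is None:
        return None
    proc = subprocess.run(["RNAfold", "--noPS"], input=normalize(seq),
                          capture_output=True, text=True, check=True)
    line = proc.stdout.splitlines()[1]
    db, _, rest = line.partition(" ")
    return db, float(rest.strip().strip("()"))
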