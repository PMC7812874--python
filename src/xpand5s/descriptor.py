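"""RNAMotif-style structural descriptors: parse and scan.

A descriptor is an ordered list of blocks — IUPAC motif blocks and bounded
variable-length gaps — plus antiparallel base-pairing constraints between
equal-length sub-ranges of two motif blocks.  The grammar (one block or
constraint per line, ``#`` comments):

    YYYGGYGRY            a motif block (bare IUPAC string; T == U)
    N[50:180]            a gap of 50 to 180 arbitrary nucleotides
    pair(block1[0:8], block5[0:8], wobble=yes)
                         positions 0..7 of block 1 pair antiparallel with
                         positions 0..7 of block 5 (blocks numbered from 1
                         in written order; ranges 0-based half-open)

Constraints are evaluated on the concrete matched bases: position ``k`` of
the 5' sub-range against position ``len-1-k`` of the 3' sub-range.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass
from pathlib import Path

from .iupac import EXPANSION, bases_pair, normalize, reverse_complement


class DescriptorError(ValueError):
    pass


@dataclass(frozen=True)
class MotifBlock:
    pattern: str

    def __len__(self) -> int:
        return len(self.pattern)


@dataclass(frozen=True)
class GapBlock:
    lo: int
    hi: int


@dataclass(frozen=True)
class PairConstraint:
    block_a: int               # 0-based block index
    range_a: tuple[int, int]   # 0-based half-open within block_a
    block_b: int
    range_b: tuple[int, int]
    wobble: bool = False


@dataclass(frozen=True)
class Descriptor:
    blocks: tuple
    constraints: tuple[PairConstraint, ...] = ()
    name: str = "descriptor"

    def __post_init__(self) -> None:
        if not self.blocks:
            raise DescriptorError("descriptor has no blocks")
        for b in self.blocks:
            if isinstance(b, GapBlock):
                if b.lo > b.hi or b.lo < 0:
                    raise DescriptorError(f"invalid gap bounds [{b.lo}:{b.hi}]")
            elif isinstance(b, MotifBlock):
                bad = set(b.pattern) - set(EXPANSION)
                if bad or not b.pattern:
                    raise DescriptorError(f"invalid IUPAC motif {b.pattern!r}")
            else:
                raise DescriptorError(f"unknown block {b!r}")
        for c in self.constraints:
            for bi, (x, y) in ((c.block_a, c.range_a), (c.block_b, c.range_b)):
                if not 0 <= bi < len(self.blocks):
                    raise DescriptorError(f"constraint names missing block {bi + 1}")
                blk = self.blocks[bi]
                if not isinstance(blk, MotifBlock):
                    raise DescriptorError("constraints must reference motif blocks")
                if not (0 <= x < y <= len(blk.pattern)):
                    raise DescriptorError(f"bad constraint range [{x}:{y}]")
            if (c.range_a[1] - c.range_a[0]) != (c.range_b[1] - c.range_b[0]):
                raise DescriptorError("constraint sub-ranges differ in length")

    @property
    def motifs(self) -> list[MotifBlock]:
        return [b for b in self.blocks if isinstance(b, MotifBlock)]

    @property
    def min_span(self) -> int:
        return sum(len(b) if isinstance(b, MotifBlock) else b.lo
                   for b in self.blocks)

    @property
    def max_span(self) -> int:
        return sum(len(b) if isinstance(b, MotifBlock) else b.hi
                   for b in self.blocks)


@dataclass(frozen=True)
class DescriptorHit:
    """Block spans on the forward coordinate system, 0-based half-open."""

    seq_id: str
    strand: str
    spans: tuple[tuple[int, int], ...]

    @property
    def start(self) -> int:
        return self.spans[0][0]

    @property
    def end(self) -> int:
        return self.spans[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_GAP_RE = re.compile(r"^N\[(\d+):(\d+)\]$")
_PAIR_RE = re.compile(
    r"^pair\(\s*block(\d+)\[(\d+):(\d+)\]\s*,\s*block(\d+)\[(\d+):(\d+)\]\s*"
    r"(?:,\s*wobble=(yes|no)\s*)?\)$"
)


def parse_descriptor(text: str, name: str = "descriptor") -> Descriptor:
    """Parse descriptor text in the grammar documented at module level."""
    blocks: list = []
    constraints: list[PairConstraint] = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _GAP_RE.match(line)
        if m:
            lo, hi = int(m.group(1)), int(m.group(2))
            if lo > hi:
                raise DescriptorError(f"inverted gap bounds in {line!r}")
            blocks.append(GapBlock(lo, hi))
            continue
        m = _PAIR_RE.match(line)
        if m:
            constraints.append(PairConstraint(
                block_a=int(m.group(1)) - 1,
                range_a=(int(m.group(2)), int(m.group(3))),
                block_b=int(m.group(4)) - 1,
                range_b=(int(m.group(5)), int(m.group(6))),
                wobble=(m.group(7) == "yes"),
            ))
            continue
        if line.startswith("pair(") or "[" in line:
            raise DescriptorError(f"cannot parse descriptor line {line!r}")
        pattern = normalize(line)
        if set(pattern) - set(EXPANSION):
            raise DescriptorError(f"unknown IUPAC code in motif {line!r}")
        blocks.append(MotifBlock(pattern))
    return Descriptor(tuple(blocks), tuple(constraints), name=name)


def load_descriptor(path) -> Descriptor:
    path = Path(path)
    return parse_descriptor(path.read_text(), name=path.stem)


def packaged_descriptor(name: str) -> Descriptor:
    """Load a shipped pattern: ``"thermoanaerobacterales"`` or ``"halobacteria"``."""
    res = importlib.resources.files("xpand5s.data").joinpath(f"{name}.descr")
    try:
        text = res.read_text()
    except FileNotFoundError:
        raise DescriptorError(f"no packaged descriptor {name!r}") from None
    return parse_descriptor(text, name=name)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _motif_positions(seq: str, pattern: str) -> list[int]:
    """Start offsets where the IUPAC pattern matches (naive position-wise)."""
    L, out = len(pattern), []
    sets = [EXPANSION[c] for c in pattern]
    for p in range(len(seq) - L + 1):
        for k in range(L):
            if seq[p + k] not in sets[k]:
                break
        else:
            out.append(p)
    return out


def _check_constraints(seq: str, d: Descriptor,
                       placements: dict[int, int]) -> bool:
    for c in d.constraints:
        pa = placements[c.block_a] + c.range_a[0]
        pb = placements[c.block_b] + c.range_b[0]
        L = c.range_a[1] - c.range_a[0]
        for k in range(L):
            if not bases_pair(seq[pa + k], seq[pb + L - 1 - k], c.wobble):
                return False
    return True


def _scan_forward(seq: str, seq_id: str, d: Descriptor, strand: str,
                  seq_len: int) -> list[DescriptorHit]:
    """All satisfying placements on one strand of ``seq``.

    Motif occurrences are enumerated per motif first (anchor lists), then
    chained left-to-right under the gap bounds; constraints are evaluated on
    the concrete matched bases.
    """
    motif_ids = [i for i, b in enumerate(d.blocks) if isinstance(b, MotifBlock)]
    if not motif_ids:
        return []
    occ = {i: _motif_positions(seq, d.blocks[i].pattern) for i in motif_ids}
    if any(not occ[i] for i in motif_ids) :
        return []

    # gap bounds between consecutive motifs (sums of any interleaved gaps)
    gaps: list[tuple[int, int]] = []
    for a, b in zip(motif_ids, motif_ids[1:]):
        lo = sum(d.blocks[k].lo for k in range(a + 1, b)
                 if isinstance(d.blocks[k], GapBlock))
        hi = sum(d.blocks[k].hi for k in range(a + 1, b)
                 if isinstance(d.blocks[k], GapBlock))
        gaps.append((lo, hi))

    hits: list[DescriptorHit] = []
    chain: list[int] = []

    def _extend(level: int) -> None:
        if level == len(motif_ids):
            placements = {mid: pos for mid, pos in zip(motif_ids, chain)}
            if _check_constraints(seq, d, placements):
                hits.append(_build_hit(seq_id, d, motif_ids, chain, strand,
                                       seq_len))
            return
        if level == 0:
            for p in occ[motif_ids[0]]:
                chain.append(p)
                _extend(1)
                chain.pop()
            return
        prev_end = chain[-1] + len(d.blocks[motif_ids[level - 1]])
        lo, hi = gaps[level - 1]
        for p in occ[motif_ids[level]]:
            if p < prev_end + lo:
                continue
            if p > prev_end + hi:
                break
            chain.append(p)
            _extend(level + 1)
            chain.pop()

    _extend(0)
    return hits


def _build_hit(seq_id: str, d: Descriptor, motif_ids: list[int],
               chain: list[int], strand: str, seq_len: int) -> DescriptorHit:
    spans = []
    pos_by_block = dict(zip(motif_ids, chain))
    cursor = None
    for i, b in enumerate(d.blocks):
        if isinstance(b, MotifBlock):
            s = pos_by_block[i]
            spans.append((s, s + len(b)))
            cursor = s + len(b)
        else:
            # gap span: from end of previous block to start of next motif
            nxt = next(pos_by_block[j] for j in motif_ids if j > i)
            spans.append((cursor, nxt))
            cursor = nxt
    if strand == "-":
        spans = [(seq_len - e, seq_len - s) for (s, e) in reversed(spans)]
    return DescriptorHit(seq_id=seq_id, strand=strand, spans=tuple(spans))


def scan_descriptor(seq: str, d: Descriptor, both_strands: bool = False,
                    seq_id: str = "seq") -> list[DescriptorHit]:
    """All placements of ``d`` in ``seq`` (and optionally its reverse
    complement), in ascending start order, deduplicated by exact span tuple.
    Minus-strand hits are reported in forward coordinates."""
    s = normalize(seq)
    hits = _scan_forward(s, seq_id, d, "+", len(s))
    if both_strands:
        hits += _scan_forward(reverse_complement(s), seq_id, d, "-", len(s))
    seen = set()
    out = []
    for h in sorted(hits, key=lambda h: (h.start, h.end, h.strand, h.spans)):
        key = (h.strand, h.spans)
        if key not in seen:
            seen.add(key)
            out.append(h)
    return out
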