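# Methods

`xpand5s` finds and annotates expansion segments — taxon-specific sequence
stretches inserted between the universally conserved elements — in
prokaryotic 5S ribosomal RNAs. This note describes the models and
procedures the package implements, the parameters that matter, what the
synthetic-data generator does and does not emulate, and the numerical
choices behind deterministic results.

## Universal numbering

Residues of the conserved 5S core carry integer labels on the E. coli
anchored scale (positions 1–120). Residues absent from the archetype carry
decimal-fraction labels extending the nearest upstream core position
(89.1, 104.1); insertions nested under such a column get a further level
(104.1.1). Labels form a strict total order consistent with 5'→3'
residue order: a prefix precedes its extensions, extensions compare by the
first differing index. The second nesting level is an extension beyond the
single level seen in published catalogs; it closes the labelling algebra,
so an insertion after any labelled residue is itself labelable.

Two core schemas ship as YAML data files:

* **bacterial** — realised by the canonical 120-nt E. coli 5S rRNA, the
  family's structural archetype;
* **archaeal** — realised by a *constructed* Halobacterium-type fixture
  (clearly marked synthetic in the data file). No complete archaeal
  reference sequence is printed in text form in the material this package
  reproduces, so the fixture was designed to satisfy every structural
  constraint the numbering needs: the G7–C113 helix I landmark, the
  U77–A99 and A78–G98 interactions bracketing helix IV, a single-residue
  loop E bulge between positions 76 and 77 (column 76.1), the
  archaea-specific column 104.1, and the Halobacteria search pattern
  (MGGCGGCC…BNNMSUACU…TCGCCGCC with helix-I pairing).

Both schemas label the fourth loop D base 89.1 (87, 88, 89, 89.1). For the
E. coli realisation this is reconciled with the helix IV landmarks by not
realising integer column 92 in the archetype — one helix-IV stem column of
the generalised model has no E. coli counterpart in this numbering. This
is the package's own approximation: the generalised secondary-structure
model it abstracts is a diagram, and per-column consensus codes are not
recoverable from text. Consensus codes are therefore exact at landmark
columns, descriptor-derived IUPAC codes over the three anchor windows, and
N elsewhere; structural-element assignments (helix I–V, loops A–E,
junction) are approximate ranges and intended for orientation, not for
structure prediction.

## Core alignment (`align_to_core`)

Numbering a query is anchor-seeded: the three conserved core fragments
(core residues 3–11, 72–80, 109–117 — the same fragments the descriptor
search fixes) are located in the query allowing at most one mismatch each;
the colinear seed chain with fewest mismatches wins. The stretches
between and outside the anchors are aligned to the corresponding schema
columns by global affine-gap alignment (match +2, mismatch −1, gap open
−6, extend −1; a length-L gap costs 6 + L). A large insertion then costs
one gap opening instead of quadratic search. Query residues aligned to a
schema column take that column's label (core state); residues falling in
query-only gaps take decimal labels extending the nearest upstream core
label (insertion state); unoccupied schema columns are simply skipped
(deletions). Records in which any anchor cannot be seeded cannot be
numbered and raise an alignment failure — this is how terminally truncated
pseudogene remnants surface when they sneak past the size filter. A map
whose landmark columns received consensus-incompatible residues is flagged
low-confidence rather than rejected.

Maximal runs of insertion-state residues of at least `min_len` (default
10 nt) become expansion segments, reported with the flanking core-label
pair as the insertion site. The 10-nt floor separates segments from
ordinary 1–2 nt indels; the smallest documented segment is 13 nt.

**Boundary ambiguity.** When an inserted run's terminal base equals the
adjacent core base, placements shifted by one column have identical
alignment score — the same molecule is the truth for two different sites.
Mutations immediately flanking a junction can even make a shifted
placement score better. No aligner can resolve this from sequence alone;
the synthetic generator therefore builds implants whose edges differ from
their flanks and keeps a ±2-column window around each site unmutated, so
that implanted truths are well defined. On real data, reported sites
should be read with this one-column caveat in mind.

## Descriptor scanning (`descriptor_scan`)

Descriptors are the block/gap/pair subset of RNAMotif-style patterns: IUPAC
motif blocks, bounded gaps `N[lo:hi]`, and antiparallel pairing constraints
between equal-length sub-ranges of two motifs. Two files ship:

* Thermoanaerobacterales: `YYYGGYGRY N[50:180] GAUGRUASU N[20:150]
  YYGCCRRR`, 5'-terminal 8-mer paired with the 3' fragment;
* Halobacteria: `MGGCGGCC N[50:180] BNNMSUACU N[20:150] TCGCCGCC`, GGCGGC
  paired with GCCGCC.

The second gap's bounds follow the methods-section value (20–150). Both
shipped files set `wobble=yes` on the pairing constraint: the E. coli
archetype's own helix I contains a G·U pair at the constrained positions,
so a strict Watson–Crick constraint would reject the archetype; G·U is
also standard in RNA helix pairsets. The API default for constraint
evaluation remains Watson–Crick only. Constraints are evaluated on the
concrete matched bases (position k of the 5' fragment against position
len−1−k of the 3' fragment), not on code compatibility.

The scanner enumerates motif occurrences first and chains them under the
gap bounds; hits are reported in ascending start order, deduplicated by
exact span tuple, minus-strand hits in mirrored forward coordinates. For
the shipped pattern the minimal/maximal hit spans are 96/356 nt, an
arithmetic consequence of the pattern. The implementation is verified
exactly against exhaustive placement enumeration in the test suite.

## Split-hit insertion detection (`insertion_detect`)

The genomic screen looks for a normal 5S query whose 5' and 3' parts make
separate colinear local hits to a genome at a distance compatible with an
intervening insertion. Local alignment is exact affine Smith–Waterman
(match +2, mismatch −3, gap 5 + 2L, BLASTN-like defaults) computed by
Biopython's PairwiseAligner, with suboptimal hits obtained by recursively
re-searching the subject flanks, so hits never overlap on the subject.
Because an exact optimum bridges a 13–109-nt insertion as a single
internal gap whenever the flank beyond it pays for the gap (a heuristic
X-dropoff search would stop instead), optimal hits are additionally
decomposed at subject-side gaps of at least `delta_range[0]` before
pairing — the split-hit signature is recovered with exact arithmetic
either way.

Pairing requires same strand, colinearity, a query gap within
[−5, +10] nt (the query is contiguous across a genuine junction; the upper
bound prevents pairing across an intervening third hit), and an insertion
length `delta = subject gap − query gap` within `delta_range` (default
10–250 nt, bracketing the documented 13–109 with margin so detection does
not hard-code the discovered extremes). Query overlaps of 6–45 nt are
reconciled by trimming the hit whose overlapping stretch aligns worse —
local hits over-extend past junctions by chance similarity — and within
the 0–5 nt micro-homology band the break is the overlap midpoint, ties
toward 5'. Half-hits must be at least 12 nt at 70 % identity with score
≥ 20: the flank downstream of the 3'-most documented sites (104.1–105,
105–106) is only 15–17 nt, so a larger length floor would make those
geometries undetectable in principle.

Full-coverage single hits at ≥ 90 % identity are reported separately as
normal-gene matches; everything else above threshold is a partial hit used
by the validity screen.

**Validity filters.** Records are size-filtered (≥ 130 nt — the threshold
that defines "oversized" relative to a ~120-nt normal 5S) and must be free
of ambiguity codes. Internal duplication is detected by Smith–Waterman of
a record against itself with the near-diagonal band (offset < 40)
forbidden; a hit of ≥ 40 nt at ≥ 85 % identity is a duplication. Chimeras
are detected by comparing best hits of the record's 5' and 3' halves
against the reference set: different references of < 80 % mutual identity,
or a truly reversed arrangement on one reference, flag the record. A
moderate same-reference overlap of the half-hits is expected (hits
over-extend past the midpoint) and is not chimeric.

## Structural typing (`annotate_classify`)

Molecules are partitioned by insertion-site signature (the multiset of
sites over a molecule's segments); each signature class is one structural
type. Within a type, molecules are clustered by single linkage on global
alignment identity of their site-ordered concatenated segments, with the
shorter sequence as denominator (segments of one family vary in length,
e.g. 41–46 nt within the thermoanaerobacterial type); clusters at the
default 60 % threshold are reported as subtypes. The published material
never defines its typing rule; this operationalisation reproduces the
published behaviour of one type with three phylogenetically coherent
subtypes, and both the threshold and the rule are recorded in output
metadata. Type identifiers are deterministic (ordered by first site, then
exemplar sequence) and invariant under input permutation; raising the
threshold only refines clusters.

## Folding checks (`structure_check`)

Expansion segments are expected to fold as self-contained modules. The
shipped criterion is base-pair maximisation (Nussinov dynamic programming)
over Watson–Crick plus optional G·U pairs with hairpin loops ≥ 3 nt —
reproducible with no thermodynamic tables; free-energy folding is
deliberately out of scope, and an optional hook can shell out to RNAfold
for side-by-side comparison. Traceback is deterministic: the 3' residue
of an interval pairs with its smallest admissible partner whenever pairing
attains the maximum. `segment_independence` reports the segment's internal
pairing fraction (2·pairs/length) and the longest exactly
reverse-complementary run between segment and core — self-contained
segments score high on the first and low on the second.

## Synthetic genomes (`synthetic`)

The generator emulates the discovery scenarios: normal genes (~120 nt,
seeded substitutions at non-conserved columns only, default rate 0.02 per
site to mimic strain-level divergence from the schema reference), expanded
genes (1–3 hairpin implants per molecule, lengths 13–109 nt, sites drawn
from the documented inventory including the helix III bulge 52–53, loop C
34–37, the helix IV region, and the archaeal 104.1–105), pseudogene
remnants (35 nt removed from each terminus, insertion retained, central
sites so both flanks stay alignable — the reconstructed record then falls
below the 130-nt filter), chimeras (bacterial 5' half joined to an
archaeal 3' half), and tandem duplications (a gene followed by its first
60 nt). Features are placed on either strand in uniform-composition
background (GC adjustable, halophile/thermophile genomes skew) with
Poisson-distributed intergenic gaps (mean 300 nt). A single integer seed
drives a named substream per stage and feature, so outputs are
byte-identical per seed and adding stages never perturbs earlier output.

`generate_study_genomes` builds the study-scale set used by the acceptance
checks: 54 expanded-gene recipes over 9 genomes covering ≥ 10 distinct
sites, the documented 46-nt (52–53) and 108-nt (104.1–105) geometries,
lengths spanning exactly 13–109, plus remnants, chimeras and duplications
in every genome. The sizes were chosen to exercise every documented
condition while keeping a full run in seconds on one CPU.

**What passing on synthetic data does not show.** The generator produces
substitution-only divergence (no indels in the core), uniform random
background, hairpin-clean implants with well-defined junctions, and exact
schema-length cores. Real genomes contain core indels, compositional
structure, repeated elements, and insertions whose edges blend into the
core — detection there inherits the boundary caveat above, and the
validity screens (not the detector) carry more of the burden.

## Pipeline and I/O

`run_pipeline` chains scan → detect → prefilter → validate → annotate →
classify → summarize. Every filter logs its rejections with reasons, the
parameter set is embedded verbatim in the log, record counts balance at
every stage, and reruns with identical inputs produce byte-identical
TSV/GFF3/JSON outputs. Coordinates are 0-based half-open internally and in
TSV/BED; GFF3 output is 1-based inclusive, converted at the boundary and
stated in every header. A contaminated locus counts as flagged whether it
surfaced through the suspicious-locus screen or as a candidate record
rejected by the validity filters; the two paths are deduplicated by span.

## Known limitations

* Site assignment at junctions with edge homology is ambiguous by one
  column (see above).
* The archaeal schema is a designed fixture, not a database sequence;
  numbering of real archaeal 5S rRNAs should be validated against their
  own references before interpretation.
* The chimera test needs at least two references and returns an
  indeterminate verdict otherwise.
* The scanner is exact but naive (no suffix-automaton seeding); it is
  intended for desk-scale screens, not nucleotide databases.
* Segment typing at the default 60 % identity is a convention; published
  catalogs may split or lump differently.
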