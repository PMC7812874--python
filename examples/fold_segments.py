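"""Check that an expansion segment folds as a self-contained module.

Folds a designed hairpin by base-pair maximisation and scores its
independence from the 5S core: high internal pairing, no long
complementary run against the core.
"""

from xpand5s import fold_max_pairing, load_schema, segment_independence
from xpand5s.synthetic import generate_hairpin_segment

core = load_schema("bacterial").reference_sequence
segment = generate_hairpin_segment(stem=14, loop=4, bulges=2, seed=4)

fold = fold_max_pairing(segment)
print(f"segment ({len(segment)} nt): {fold.sequence}")
print(f"fold:               {fold.dot_bracket}")
print(f"pairs: {fold.pair_count}, internal fraction "
      f"{fold.internal_fraction:.2f} (fraction of residues in pairs)")

internal, cross = segment_independence(segment, core)
print(f"longest reverse-complementary run against the core: {cross} nt")
print("High internal pairing with a short cross-run means the segment can "
      "fold on its own without competing with core helices.")
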