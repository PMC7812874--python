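"""Scan a sequence with the shipped 5S rRNA structural descriptors.

Builds a small genome fragment containing the E. coli 5S archetype and
scans it with the Thermoanaerobacterales pattern (three conserved core
fragments separated by bounded spacers, with helix-I pairing).
"""

from xpand5s import load_schema, packaged_descriptor, scan_descriptor

schema = load_schema("bacterial")
descriptor = packaged_descriptor("thermoanaerobacterales")
fragment = "AU" * 40 + schema.reference_sequence + "GC" * 40

hits = scan_descriptor(fragment, descriptor, both_strands=True, seq_id="demo")
print(f"pattern: {descriptor.name}, admissible hit span "
      f"{descriptor.min_span}-{descriptor.max_span} nt")
for h in hits:
    spans = ", ".join(f"{s}-{e}" for s, e in h.spans)
    print(f"hit on strand {h.strand} at {h.start}-{h.end} (blocks: {spans})")
print("Each hit is a candidate 5S rRNA locus: three conserved fragments in "
      "order, spacer lengths within bounds, helix I paired.")
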