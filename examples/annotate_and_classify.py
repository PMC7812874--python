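"""Number an expanded 5S rRNA against the universal core and type it.

Builds the documented halococcal geometry (108-nt insertion between
archaeal core positions 104.1 and 105) and annotates it.
"""

from xpand5s import annotate_record, load_schema
from xpand5s.classify import Molecule, classify_structural_types
from xpand5s.labels import parse_position_label as P
from xpand5s.synthetic import hairpin_for_length, implant_segment

schema = load_schema("archaeal")
ref = schema.reference_sequence
i = schema.index_of(P("104.1"))
segment = hairpin_for_length(108, seed=2, flank5=ref[i], flank3=ref[i + 1])
expanded, _ = implant_segment(ref, (P("104.1"), P("105")), segment,
                              schema=schema)

cmap, segments = annotate_record(expanded, schema, record_id="demo",
                                 taxon="halophilic archaeon")
print(f"record length {len(expanded)} nt, alignment score {cmap.score:.0f}")
for s in segments:
    print(f"expansion segment: site {s.site_str}, {s.length} nt, "
          f"starts at residue offset {s.start}")
    first = cmap.assignments[s.start]
    print(f"first inserted residue is labelled {first.label} "
          f"(decimal labels extend the upstream core position)")

molecules = [Molecule("demo", "halophilic archaeon", tuple(segments))]
types = classify_structural_types(molecules)
print(f"structural types: {[t.type_id for t in types]} with site signatures "
      f"{[t.site_signature for t in types]}")
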