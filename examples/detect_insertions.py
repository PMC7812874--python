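"""Find an expanded 5S gene in genomic DNA by split-hit detection.

Implants the documented 46-nt thermoanaerobacterial geometry (helix III
bulge, site 52-53) into a synthetic genome and screens it with the normal
E. coli 5S as query.
"""

from xpand5s import ExpandedSpec, GenomePlan, find_split_candidates, load_schema
from xpand5s.synthetic import generate_genome

plan = GenomePlan(n_normal=1, n_expanded=1, n_pseudogene=0,
                  expanded_specs=(ExpandedSpec("bacterial", ("52-53",), (46,)),))
genome = generate_genome(plan, seed=17)
schema = load_schema("bacterial")

result = find_split_candidates(schema.reference_sequence, genome.sequence,
                               reference_id=schema.reference_id,
                               genome_id=genome.genome_id)
print(f"normal-gene matches: {len(result.normal_matches)}")
for c in result.candidates:
    print(f"split candidate on {c.strand}: gene {c.gene_start}-{c.gene_end}, "
          f"insertion {c.insertion_start}-{c.insertion_end} "
          f"({c.insertion_length} nt), break after query position "
          f"{c.break_query_pos}")
print("The 5' and 3' parts of the query hit the genome separately; the "
      "subject-side gap minus the query-side gap is the insertion length.")
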