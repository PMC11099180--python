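"""Significant intersection sets: introducing sets, additional
organizations, and the family of core microbiomes.

The full intersection closure of the measurements is huge; the analysis
keeps only the intents that either introduce a taxon (the smallest
context a taxon was ever seen in) or are simultaneously an intersection
and a union of measurements (predicted persistent communities).
"""

import orglattice as ol

table, truth = ol.make_planted_table(ol.hainich_like(seed=1))

closure = ol.intersection_closure(table.taxa_sets())
intro = ol.introducing_sets(table)
extra = ol.additional_organizations(table)
print(f"concept intents (all intersections): {len(closure)}")
print(f"introducing sets: {len(intro)}; additional organizations: {len(extra)}")
print(f"  -> the analysis reduces {len(closure)} intents to "
      f"{len(intro) + len(extra)} significant ones")

cores = ol.core_microbiomes(table, support_fraction=0.9)
big = ol.largest_core(cores)
small = ol.smallest_core(cores)
print(f"core microbiomes (>=90% support): {len(cores)}")
print(f"  largest: {len(big.intent)} taxa in {big.support} samples "
      f"{sorted(big.intent.labels())}")
print(f"  smallest (always-present core): {sorted(small.intent.labels())}")
print("planted global core was:", sorted(truth.global_core.labels()))

sig = ol.significant_lattice(table)
kinds = [n.kind for n in sig.nodes]
print(f"significant lattice: {sig.n_nodes} nodes "
      f"({kinds.count('measurement')} measurements, "
      f"{kinds.count('intersection')} introducing intersections, "
      f"{kinds.count('additional_organization')} additional organizations)")
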