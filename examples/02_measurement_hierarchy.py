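"""Build the subset-order Hasse diagram of a community time series.

Generates a synthetic four-well, 30-month presence/absence table with a
planted hierarchy, then reports how interconnected the measurements are
and how long the bottom-to-top chains of growing communities get.
"""

import orglattice as ol

table, truth = ol.make_planted_table(ol.hainich_like(seed=1))
sets = table.taxa_sets()
print(f"{table.n_samples} samples over {table.universe.size} taxa; "
      f"{len(ol.distinct_sets(sets))} distinct taxa sets")

rep = ol.connectivity_counts(sets)
print(f"fraction of measurements with a sub- or superset relation: "
      f"{rep.frac_connected:.2f} "
      f"(subset of another: {rep.frac_with_superset:.2f}, "
      f"containing another: {rep.frac_with_subset:.2f})")

h = ol.build_hasse(sets, include_bounds=True, table=table)
hist = ol.path_histogram(h)
print(f"bottom-to-top paths: {hist.total_paths}, by length: {hist.counts}")
print("a path of length L climbs from the empty set to the union of all "
      "measured taxa through L-1 intermediate communities")
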