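"""Virtual subsampling: how many organizations become derivable as
measurements accumulate?

Organizations are inserted one at a time in random order; after each
insertion we count the sets that are simultaneously an intersection and
a union of at least two inserted sets without having been inserted —
communities we would predict before observing them.
"""

import orglattice as ol

# three disjoint motifs, each hiding one derivable organization
table, expected = ol.make_additional_org_instance(3)
family = ol.distinct_sets(table.taxa_sets())
family.append(table.universe.empty())

curve = ol.subsample_curve(family, n_repeats=100, seed=7)
peak = max(range(len(curve.means)), key=lambda i: curve.means[i])
print(f"family of {len(family)} organizations, 100 random insertion orders")
print(f"peak of the mean curve: {curve.means[peak]:.2f} derivable additional "
      f"organizations after {curve.steps[peak]} insertions")
print(f"final step: min={curve.mins[-1]} mean={curve.means[-1]:.2f} "
      f"max={curve.maxs[-1]} (all inserted; matches the direct count "
      f"{len(ol.additional_organizations(family))})")
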