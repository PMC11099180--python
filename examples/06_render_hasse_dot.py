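"""Emit an annotated Hasse diagram as Graphviz DOT.

Node labels follow the lattice-node schema: id, taxa count,
(supersets, subsets), the introduced taxa, and one colored box per well
listing supporting time points.  Grey fill = self-maintaining, colored
border = measurement.
"""

import orglattice as ol
from orglattice.render import to_dot

u = ol.TaxaUniverse(list("abcxy"))
sets = [u.set_of("ab"), u.set_of("ac"), u.set_of("abcx"), u.set_of("abcy")]
table = ol.MeasurementTable(
    u, [ol.SampleRecord(f"H41:{i}", "H41", i, s) for i, s in enumerate(sets)]
)
sig = ol.significant_lattice(table)
dot = to_dot(sig, table=table)
print(dot)
print("// pipe into `dot -Tsvg` to rasterize; the grey black-bordered",
      "node is the additional organization {a,b,c}")
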