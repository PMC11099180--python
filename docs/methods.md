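# Methods

## Model and assumptions

The analysis treats each sample of a community survey as a set of taxa
(presence/absence only) and studies the partial order these sets form
under inclusion. Its dynamical interpretation rests on two
assumptions:

1. **Replicator-style kinetics.** Taxa arise only by inflow
   (`-> a`), self-replication (`b -> 2 b`) or replication assisted by
   other taxa (`e + b + c -> b + c + 2 e`), and every taxon decays
   (`a ->`). Under this structure the organizations of the (unknown)
   interaction network form a lattice, the union of two organizations
   is again self-maintaining, and the intersection of two organizations
   is again closed.
2. **Stationarity of measurements.** Each sample is taken from a
   persistent state, so each measured taxa set is an organization of
   the underlying network.

Because of assumption 1 a simplified self-maintenance test suffices:
a set is self-maintaining iff every member has at least one active
reaction whose product coefficient for that member exceeds its
reactant coefficient. The general flux-vector (linear-programming)
formulation of chemical organization theory is deliberately out of
scope. Reaction *activity* is presence/absence only — a reaction is
active on a set iff all its reactant species are members; coefficient
magnitudes never matter for activity, and decay reactions never count
against self-maintenance. Negative interactions (inhibition,
competition) are not representable; if they matter in a system, unions
of organizations may fail to be self-maintaining and the lattice
interpretation weakens accordingly.

## Definitions

For a measurement family *M* (distinct taxa sets) over a universe of
*n* taxa:

* **intersection closure** — smallest family containing *M* closed
  under pairwise intersection; equals the set of concept intents of the
  sample × taxa context. The empty set is a member iff it arises as an
  intersection.
* **introducing set (attribute concept)** of taxon *t* — intersection
  of all measurements containing *t*; taxa with identical attribute
  concepts are reported together, as the taxa that set *introduces*.
* **additional organization** — a set *S* ∉ *M* such that (i) *S*
  equals the intersection of the ≥ 2 measurements containing it and
  (ii) *S* equals the union of the ≥ 2 measurements contained in it.
  Condition (i) is the concept-intent reading of "intersection of at
  least two measurements".
* **core microbiome family** at support fraction *f* — all concept
  intents whose extent has at least ⌈*f·n_samples*⌉ samples, excluding
  the empty intent (ceiling, so 90 % of 114 samples means ≥ 103).
* **Hasse diagram** — the covering relation (transitive reduction) of
  the subset order on a node family; drawn bottom-to-top by set size.
  Virtual bounds (empty set below, union of all measured taxa above)
  are added **only when absent**: if a measurement already equals the
  union of all measurements it doubles as the top node. Path length
  counts edges, so an isolated measurement lies on a bottom–top path of
  length 2 whenever both bounds are virtual.
* Node annotations: `support` lists the samples whose taxa set
  contains the node's set; `introduced` is the node's taxa minus the
  union of its proper-subset nodes within the same diagram;
  `n_supersets`/`n_subsets` count **measurement** nodes only, so bounds
  and intersection nodes never inflate them. Measurements and
  additional organizations are flagged self-maintaining (grey fill in
  DOT); plain intersections are only closed.

## Algorithms and numerical choices

* Taxa sets are bitmasks over the universe's abundance-rank order; all
  set algebra is integer bitwise arithmetic, with a vectorized uint64
  path for universes of ≤ 63 taxa and a plain-integer fallback above.
* **Closure by a single fold.** The family closed under pairwise
  intersection with base sets m₁…m_k is obtained in one left-to-right
  pass (`family ∪= family ∩ m_j`): any ∩_{i∈T} m_i with max(T) = j
  equals (∩_{T∖{j}} m_i) ∩ m_j, and the inner term exists before step
  *j* by induction on max(T). The same holds for unions.
* **Additional organizations without the full closure.** A qualifying
  *S* contains some measurement *m*, and every measurement containing
  *S* lies in the superset cone of *m*; so candidates are the local
  intersection closures of each measurement's cone, which stay small
  even when the global closure has millions of members (randomized
  tables). Each candidate is then checked against conditions (i) and
  (ii) exactly. The cone route is verified against a full-closure
  brute-force oracle in the test suite.
* **Core microbiomes by iceberg search.** Starting from the top
  concept (all samples), extents are refined one taxon at a time and
  extents below the support threshold are never expanded; only frequent
  concepts are ever materialized. Refined extents are automatically
  Galois-closed, so the search enumerates exactly the concepts above
  threshold.
* **Path census.** Exact per-length counts by dynamic programming over
  the DAG; explicit enumeration is a separate function and both are
  guarded (default 10⁶ paths) against path explosion. The DP is checked
  against DFS enumeration.
* **Determinism.** Node ids and all output orderings are assigned by
  (set size, lexicographic membership); identical inputs give
  byte-identical JSON/DOT/GraphML. Any published node ids from other
  implementations are artifacts of those implementations and are not
  reproduced.
* Organization enumeration on reaction networks is an exhaustive 2ⁿ
  scan, refused above `max_species` (default 20).

## Null models

Three randomizations of the binary matrix are provided;
`column_shuffle` is the default because it preserves each taxon's
prevalence exactly while destroying all co-occurrence — the most
conservative structure destruction. `bernoulli_frequency` preserves
prevalence only in expectation but allows resizing the sample count;
`curveball_swap` preserves both margins via checkerboard trades.
Margin-preserving schemes refuse a sample count different from the
template's. Summary statistics report the sample standard deviation
(n − 1 denominator). All draws flow from one `numpy` generator seeded
by the config.

## The synthetic generator

`make_planted_table` emulates the structure of well-transect
presence/absence surveys: a small always-present **global core**, a
per-well core block (present in every sample of its well, and
"leaking" into foreign wells with probability `well_core_leak` — well
preference, not exclusivity), and a **fluctuating tail** whose
occupancy decays with abundance rank. Tail draws share a per-sample
occupancy level with weight `nestedness`: taxon *i* is present iff
*V* < *p_i*, where *V* is the sample's shared uniform level with
probability `nestedness` and a fresh uniform otherwise. This keeps each
taxon's marginal probability exactly *p_i* while making samples
partially nested along the occupancy ranking — the feature that gives
real community data its subset hierarchy.

The `hainich_like` preset (50 taxa, wells H41/H43/H51/H52, 30 monthly
time points, 3-taxon global core, 2 core taxa per well, tail occupancy
0.95·e^(−0.035·rank) floored at 0.02, nestedness 0.95, leak 0.4) was
chosen so the generated tables resemble such a survey in richness
(≈ 8–40 taxa per sample, mean ≈ 25), connectivity (> 90 % of
measurements in a subset relation), closure magnitude (order 10⁴–10⁵
intents) and a two-digit count of additional organizations. What the
generator does **not** emulate: temporal autocorrelation within wells,
seasonal cycles, taxon–taxon interactions beyond shared occupancy, and
abundance information. Tests passing on planted tables therefore
demonstrate the set machinery and the recoverability of planted
structure, not ecological realism of any particular dataset.
`make_additional_org_instance` plants exact ground truth: per motif,
measurements base∪{p}, base∪{q}, base∪{p,q,x}, base∪{p,q,y} make
base∪{p,q} an additional organization and nothing else qualifies.

Recovery tests use a leak-free variant with tail occupancy capped at
0.6 so that planted cores are exactly identifiable (the chance of a
tail taxon appearing in all 30 samples of a well, 0.6³⁰, is
negligible); the leaky preset is used where realistic cross-well
structure matters (null-model separation).

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run on: the packaged 3- and
5-species reaction networks; random replicator networks of ≤ 7 species
against a powerset oracle; random subset families of ≤ 20 sets for the
order machinery; contexts of ≤ 12 samples for the Galois checks;
planted tables of 120 samples × 50 taxa; 20 column-shuffled null
tables; and 100-repeat subsampling on a 13-set motif family. The
deposited groundwater census (114 × 50) runs only when the
non-redistributable matrix is supplied locally.

## Known limitations

* Exhaustive organization enumeration is exponential; networks beyond
  ~20 species need a different algorithm (not provided).
* The intersection closure of weakly structured tables grows into the
  millions; `intersection_closure` materializes it and is meant for
  structured data, while the significant-set, core and null-model paths
  avoid it by construction.
* `subsample_curve` recomputes the additional-organization count after
  every insertion (as the experiment prescribes); cost grows with
  family size times repeats. Families with hundreds of members and
  ≥ 1000 repeats are expensive.
* Inference of actual taxon interaction rules from the lattice is out
  of scope.
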