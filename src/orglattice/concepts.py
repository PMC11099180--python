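"""Formal concept analysis over binarized community tables.

The sample-by-taxa presence table is a formal context: samples are
objects, taxa are attributes.  A *concept* is a pair (extent, intent) of
a maximal sample set and the maximal taxa set they all share; concept
intents are exactly the intersections of measurements, so the
intersection closure of the measured taxa sets enumerates them.

Two families of intents are singled out:

* *introducing sets* (attribute concepts): for each taxon, the
  intersection of all measurements containing it — the smallest set of
  companions the taxon was ever seen with;
* *additional organizations*: non-measured intents that are at the same
  time an intersection of >=2 measurements and a union of >=2
  measurements.  Under replicator-style dynamics a union of
  organizations stays self-maintaining and an intersection stays
  closed, so such sets inherit both properties from the measurements
  and are predicted as further persistent communities.

Concept intents with near-total sample support generalize the classic
core microbiome (taxa individually present in >=90% of samples) to a
family of interrelated core sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .lattice import HasseDiagram, build_hasse, distinct_sets
from .taxa import TaxaSet, TaxaUniverse

__all__ = [
    "Concept",
    "intersection_closure",
    "attribute_concept",
    "introducing_sets",
    "additional_organizations",
    "core_microbiomes",
    "largest_core",
    "smallest_core",
    "significant_lattice",
]


@dataclass(frozen=True)
class Concept:
    """A formal concept: mutually-maximal (samples, taxa) pair."""

    extent: tuple[str, ...]
    intent: TaxaSet

    @property
    def support(self) -> int:
        return len(self.extent)


# ---------------------------------------------------------------------------
# mask-level engines (shared with the null models, which run them in bulk)
# ---------------------------------------------------------------------------


_NP_BITS = 63  # universes up to this size use the vectorized uint64 path

# A single left-to-right fold suffices to close a family under pairwise
# intersection (or union) with the base sets: any ∩_{i∈T} m_i with
# max(T)=k equals (∩_{T\{k}} m_i) & m_k, and the inner term is present
# before step k by induction on max(T).


def _fold_closure_array(base: Sequence[int], op: str) -> np.ndarray:
    """Closure of *base* under pairwise `op` ('and'/'or'); sorted uint64."""
    family = np.unique(np.array(base, dtype=np.uint64))
    for m in family.copy():
        derived = family & m if op == "and" else family | m
        family = np.union1d(family, derived)
    return family


def _fold_closure_set(base: Sequence[int], op: str) -> set[int]:
    """Python-int fallback of :func:`_fold_closure_array` (any width)."""
    family = set(base)
    for m in list(family):
        if op == "and":
            family |= {s & m for s in family}
        else:
            family |= {s | m for s in family}
    return family


def _use_numpy(base: Sequence[int]) -> bool:
    return bool(base) and max(m.bit_length() for m in base) <= _NP_BITS


def _closure_masks(meas: Sequence[int]) -> set[int]:
    """Closure of the distinct masks under pairwise intersection."""
    base = list(dict.fromkeys(meas))
    if not base:
        return set()
    if _use_numpy(base):
        return {int(x) for x in _fold_closure_array(base, "and")}
    return _fold_closure_set(base, "and")


def _additional_masks(meas: Sequence[int]) -> list[int]:
    """Masks of additional organizations of a measurement family.

    S qualifies iff S is not a measurement, S equals the intersection
    of the >=2 measurements containing it, and S equals the union of
    the >=2 measurements inside it.

    Candidate generation avoids materializing the full intersection
    closure: a qualifying S contains some measurement m, hence every
    measurement containing S lies in the superset cone of m, and S is
    an intersection of cone members.  Cones are small, so only their
    local intersection closures are enumerated.
    """
    base = list(dict.fromkeys(meas))
    if not base:
        return []
    meas_set = set(base)
    cands: set[int] = set()
    for m in base:
        cone = [s for s in base if s & m == m]
        if len(cone) < 3:  # S needs >=2 proper supersets and >=2 subsets
            continue
        cands.update(_fold_closure_set(cone, "and"))
    cands -= meas_set
    out = []
    for s in sorted(cands):
        inter, n_sup = ~0, 0
        union, n_sub = 0, 0
        for m in base:
            if m & s == s:
                inter &= m
                n_sup += 1
            if m | s == s:
                union |= m
                n_sub += 1
        if n_sup >= 2 and inter == s and n_sub >= 2 and union == s:
            out.append(s)
    return out


def _closure_and_additional(meas: Sequence[int]) -> tuple[int, list[int]]:
    """(intersection-closure size, additional organizations)."""
    return len(_closure_masks(meas)), _additional_masks(meas)


def _sorted_sets(universe: TaxaUniverse, masks) -> list[TaxaSet]:
    sets = [TaxaSet(universe, m) for m in masks]
    sets.sort(key=lambda s: s.sort_key())
    return sets


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def intersection_closure(
    sets: Sequence[TaxaSet], descending: bool = True
) -> list[TaxaSet]:
    """Smallest family containing the distinct input sets and closed
    under pairwise intersection (= all concept intents of the context).

    The empty set appears iff it is an input or arises as an
    intersection.  Order: size descending, then lexicographic on
    membership (pass ``descending=False`` for ascending size).
    """
    ds = distinct_sets(sets)
    if not ds:
        raise ValidationError("at least one taxa set is required")
    universe = ds[0].universe
    if any(s.universe != universe for s in ds):
        raise ValidationError("all sets must share one universe")
    out = [TaxaSet(universe, m) for m in _closure_masks([s.mask for s in ds])]
    if descending:
        out.sort(key=lambda s: (-len(s), s.indices()))
    else:
        out.sort(key=lambda s: s.sort_key())
    return out


def attribute_concept(taxon: str | int, table) -> TaxaSet:
    """Intersection of the taxa sets of all samples containing *taxon* —
    the smallest measured context the taxon appears in.  Always contains
    the taxon; a taxon never observed raises a validation error."""
    universe = table.universe
    i = universe.index(taxon) if isinstance(taxon, str) else int(taxon)
    if not 0 <= i < universe.size:
        raise ValidationError(f"taxon index {i} out of range")
    bit = 1 << i
    inter, seen = ~0, False
    for rec in table.samples:
        if rec.taxa.mask & bit:
            inter &= rec.taxa.mask
            seen = True
    if not seen:
        raise ValidationError(
            f"taxon {universe.labels[i]!r} does not occur in any sample"
        )
    return TaxaSet(universe, inter)


def introducing_sets(table) -> list[tuple[TaxaSet, TaxaSet]]:
    """Distinct attribute concepts with the taxa they introduce.

    Taxa sharing an attribute concept are reported together: the second
    element of each pair holds every taxon whose attribute concept is
    exactly the first element.  Ordered by (size, lexicographic)."""
    universe = table.universe
    groups: dict[int, int] = {}
    observed = 0
    for rec in table.samples:
        observed |= rec.taxa.mask
    for i in range(universe.size):
        if not observed >> i & 1:
            continue
        mask = attribute_concept(i, table).mask
        groups[mask] = groups.get(mask, 0) | (1 << i)
    out = [
        (TaxaSet(universe, m), TaxaSet(universe, intro))
        for m, intro in groups.items()
    ]
    out.sort(key=lambda p: p[0].sort_key())
    return out


def additional_organizations(source) -> list[TaxaSet]:
    """Non-measured sets that are both an intersection of >=2 and a
    union of >=2 measurements; flagged self-maintaining downstream.

    *source* may be a MeasurementTable or a sequence of TaxaSet.
    Ordered by (size, lexicographic)."""
    sets = source.taxa_sets() if hasattr(source, "taxa_sets") else list(source)
    ds = distinct_sets(sets)
    if not ds:
        raise ValidationError("at least one measurement is required")
    universe = ds[0].universe
    return _sorted_sets(universe, _additional_masks([s.mask for s in ds]))


def core_microbiomes(table, support_fraction: float = 0.9) -> list[Concept]:
    """Formal concepts whose extent covers at least
    ``ceil(support_fraction * n_samples)`` samples, excluding the empty
    intent — the family of interrelated core microbiomes.

    The minimal-intent member is the global intersection (the classic
    always-present core); ordered by (intent size, lexicographic)."""
    if not 0 < support_fraction <= 1:
        raise ValidationError("support_fraction must be in (0, 1]")
    n = len(table.samples)
    threshold = ceil(support_fraction * n)
    universe = table.universe
    masks = [rec.taxa.mask for rec in table.samples]
    ids = [rec.sample_id for rec in table.samples]

    def intent_of(extent: frozenset[int]) -> int:
        inter = ~0
        for i in extent:
            inter &= masks[i]
        return inter

    # iceberg concept search: start from the top concept (all samples)
    # and refine extents one taxon at a time; extents below the support
    # threshold are never expanded, so only frequent concepts are built
    top = frozenset(range(n))
    queue = [top]
    seen = {top}
    found: dict[int, frozenset[int]] = {}
    while queue:
        extent = queue.pop()
        intent = intent_of(extent)
        found[intent] = extent
        for x in range(universe.size):
            if intent >> x & 1:
                continue
            sub = frozenset(i for i in extent if masks[i] >> x & 1)
            if len(sub) >= threshold and sub not in seen:
                seen.add(sub)
                queue.append(sub)
    out = [
        Concept(
            tuple(ids[i] for i in sorted(extent)), TaxaSet(universe, intent)
        )
        for intent, extent in found.items()
        if intent != 0
    ]
    out.sort(key=lambda c: c.intent.sort_key())
    return out


def largest_core(cores: Sequence[Concept]) -> Concept:
    """The core with the most taxa (ties: larger support, then order)."""
    if not cores:
        raise ValidationError("no core microbiomes given")
    return max(cores, key=lambda c: (len(c.intent), c.support))


def smallest_core(cores: Sequence[Concept]) -> Concept:
    """The core with the fewest taxa — the global intersection."""
    if not cores:
        raise ValidationError("no core microbiomes given")
    return min(cores, key=lambda c: (len(c.intent), -c.support))


def significant_lattice(table) -> HasseDiagram:
    """Hasse diagram over measurements + introducing sets + additional
    organizations (+ virtual bounds), annotated per node with kind,
    support, introduced taxa, measurement-only sub/superset counts and
    self-maintenance flags (measurements and additional organizations).
    """
    measurements = distinct_sets(table.taxa_sets())
    intro = [s for s, _ in introducing_sets(table)]
    addorg = additional_organizations(table)

    kind_map: dict[TaxaSet, str] = {}
    for s in intro:
        kind_map[s] = "intersection"
    for s in addorg:
        kind_map[s] = "additional_organization"
    for s in measurements:  # measurement status wins over intersection
        kind_map[s] = "measurement"

    sm = set(measurements) | set(addorg)
    all_sets = measurements + [s for s in kind_map if s not in set(measurements)]
    return build_hasse(
        all_sets,
        include_bounds=True,
        table=table,
        kind_map=kind_map,
        self_maintaining=sm,
    )
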