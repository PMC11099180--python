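"""Subset-order analytics over measured taxa sets.

The measurements of a community time series, binarized to taxa sets,
form a partial order under set inclusion.  This module builds the Hasse
diagram (covering relation) of that order, counts sub/superset
connectivity, enumerates bottom-to-top paths and extracts ego views
around a focal set.

Conventions:

* duplicate taxa sets collapse to one node whose support lists all
  matching samples;
* the virtual bottom is the empty set and the virtual top is the union
  of all measured taxa (not the universe) — they are added only when no
  measurement already equals them;
* a node's ``n_subsets``/``n_supersets`` counters count *measurement*
  nodes only, so virtual bounds and intersection nodes never inflate
  them;
* path length counts edges, so a measurement directly connected to both
  bounds lies on a path of length 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import CapacityError, ValidationError
from .taxa import TaxaSet

__all__ = [
    "LatticeNode",
    "HasseDiagram",
    "PathHistogram",
    "ConnectivityReport",
    "distinct_sets",
    "subset_pairs",
    "covering_edges",
    "build_hasse",
    "connectivity_counts",
    "path_histogram",
    "enumerate_paths",
    "ego_view",
]

DEFAULT_MAX_PATHS = 1_000_000


@dataclass(frozen=True)
class LatticeNode:
    node_id: int
    taxa: TaxaSet
    kind: str  # measurement | intersection | additional_organization | bottom | top
    support: tuple[str, ...] = ()
    introduced: TaxaSet | None = None
    n_supersets: int = 0
    n_subsets: int = 0
    is_measurement: bool = False
    is_self_maintaining: bool = False


@dataclass(frozen=True)
class HasseDiagram:
    """Nodes (distinct taxa sets) plus covering edges (sub_id, super_id)."""

    nodes: tuple[LatticeNode, ...]
    edges: tuple[tuple[int, int], ...]

    def __post_init__(self):
        ids = [n.node_id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise ValidationError("node ids must be unique")

    def node(self, node_id: int) -> LatticeNode:
        for n in self.nodes:
            if n.node_id == node_id:
                return n
        raise ValidationError(f"no node with id {node_id}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def successors(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {n.node_id: [] for n in self.nodes}
        for u, v in self.edges:
            out[u].append(v)
        return out

    def predecessors(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {n.node_id: [] for n in self.nodes}
        for u, v in self.edges:
            out[v].append(u)
        return out

    def bottom(self) -> LatticeNode:
        """The unique source node; ValidationError if not unique."""
        preds = self.predecessors()
        sources = [n for n in self.nodes if not preds[n.node_id]]
        if len(sources) != 1:
            raise ValidationError(
                f"diagram has {len(sources)} minimal nodes; a unique bottom "
                "bound is required (build with include_bounds=True)"
            )
        return sources[0]

    def top(self) -> LatticeNode:
        succs = self.successors()
        sinks = [n for n in self.nodes if not succs[n.node_id]]
        if len(sinks) != 1:
            raise ValidationError(
                f"diagram has {len(sinks)} maximal nodes; a unique top "
                "bound is required (build with include_bounds=True)"
            )
        return sinks[0]


def distinct_sets(sets: Iterable[TaxaSet]) -> list[TaxaSet]:
    """Deduplicate, preserving first-occurrence order."""
    seen: dict[TaxaSet, None] = {}
    for s in sets:
        seen.setdefault(s, None)
    return list(seen)


def subset_pairs(sets: Sequence[TaxaSet]) -> list[tuple[int, int]]:
    """All ordered proper-subset pairs among the distinct input sets.

    Returns index pairs (i, j) into ``distinct_sets(sets)`` with
    set_i a proper subset of set_j.
    """
    ds = distinct_sets(sets)
    masks = [s.mask for s in ds]
    return [
        (i, j)
        for i in range(len(ds))
        for j in range(len(ds))
        if i != j and masks[i] & masks[j] == masks[i] and masks[i] != masks[j]
    ]


def covering_edges(masks: Sequence[int]) -> list[tuple[int, int]]:
    """Covering relation (transitive reduction of the subset DAG) on a
    list of distinct bitmasks; edges are (sub_index, super_index)."""
    n = len(masks)
    order = sorted(range(n), key=lambda i: masks[i].bit_count())
    edges = []
    for ui in range(n):
        mu = masks[ui]
        supers = [
            v for v in order
            if masks[v] != mu and masks[v] & mu == mu
        ]
        for v in supers:
            mv = masks[v]
            if not any(
                mw != mu and mw != mv and mw & mu == mu and mw & mv == mw
                for mw in (masks[w] for w in supers)
            ):
                edges.append((ui, v))
    edges.sort()
    return edges


def build_hasse(
    sets: Sequence[TaxaSet],
    include_bounds: bool = False,
    table=None,
    kind_map: Mapping[TaxaSet, str] | None = None,
    self_maintaining: Iterable[TaxaSet] | None = None,
) -> HasseDiagram:
    """Hasse diagram of the subset order on the distinct input sets.

    With ``include_bounds`` a virtual bottom (empty set) and top (union
    of all sets) are appended unless already present.  ``table`` (a
    MeasurementTable) supplies per-node support lists.  ``kind_map``
    overrides node kinds (default: every input set is a measurement).
    ``self_maintaining`` lists sets to flag as self-maintaining
    (default: the measurement nodes — measurements of a persistent state
    are organizations).

    Node ids are assigned deterministically by (set size, lexicographic
    membership).
    """
    ds = distinct_sets(sets)
    if not ds:
        raise ValidationError("at least one taxa set is required")
    universe = ds[0].universe
    if any(s.universe != universe for s in ds):
        raise ValidationError("all sets must share one universe")

    kinds: dict[TaxaSet, str] = {}
    for s in ds:
        kinds[s] = kind_map.get(s, "measurement") if kind_map else "measurement"

    if include_bounds:
        bottom = universe.empty()
        top_mask = 0
        for s in ds:
            top_mask |= s.mask
        top = TaxaSet(universe, top_mask)
        if bottom not in kinds:
            kinds[bottom] = "bottom"
            ds.append(bottom)
        if top not in kinds:
            kinds[top] = "top"
            ds.append(top)

    ds.sort(key=lambda s: s.sort_key())
    masks = [s.mask for s in ds]
    edges = covering_edges(masks)

    if self_maintaining is None:
        sm = {s for s, k in kinds.items() if k == "measurement"}
    else:
        sm = set(self_maintaining)

    meas_masks = [s.mask for s, k in kinds.items() if k == "measurement"]
    nodes = []
    for i, s in enumerate(ds):
        m = s.mask
        below = 0
        for t in masks:
            if t != m and t & m == t:
                below |= t
        support = tuple(
            rec.sample_id
            for rec in (table.samples if table is not None else ())
            if rec.taxa.mask & m == m
        )
        nodes.append(
            LatticeNode(
                node_id=i,
                taxa=s,
                kind=kinds[s],
                support=support,
                introduced=TaxaSet(universe, m & ~below),
                n_supersets=sum(
                    1 for t in meas_masks if t != m and m & t == m
                ),
                n_subsets=sum(
                    1 for t in meas_masks if t != m and t & m == t
                ),
                is_measurement=kinds[s] == "measurement",
                is_self_maintaining=s in sm,
            )
        )
    return HasseDiagram(tuple(nodes), tuple(edges))


@dataclass(frozen=True)
class ConnectivityReport:
    """Per-set sub/superset counts among distinct measured sets."""

    sets: tuple[TaxaSet, ...]
    counts: tuple[tuple[int, int], ...]  # (n_subsets, n_supersets)
    frac_with_subset: float
    frac_with_superset: float
    frac_connected: float


def connectivity_counts(sets: Sequence[TaxaSet]) -> ConnectivityReport:
    """For each distinct set: how many other distinct sets are proper
    subsets / supersets of it, plus the fractions with >=1 relation."""
    ds = distinct_sets(sets)
    masks = [s.mask for s in ds]
    counts = []
    for m in masks:
        nsub = sum(1 for t in masks if t != m and t & m == t)
        nsup = sum(1 for t in masks if t != m and m & t == m)
        counts.append((nsub, nsup))
    n = len(ds)
    with_sub = sum(1 for c in counts if c[0] > 0)
    with_sup = sum(1 for c in counts if c[1] > 0)
    conn = sum(1 for c in counts if c[0] > 0 or c[1] > 0)
    return ConnectivityReport(
        tuple(ds),
        tuple(counts),
        with_sub / n,
        with_sup / n,
        conn / n,
    )


@dataclass(frozen=True)
class PathHistogram:
    """Distinct bottom-to-top path counts keyed by edge length."""

    counts: dict[int, int] = field(default_factory=dict)

    @property
    def total_paths(self) -> int:
        return sum(self.counts.values())

    @property
    def max_length(self) -> int:
        return max(self.counts) if self.counts else 0


def _topo_order(h: HasseDiagram) -> list[int]:
    preds = h.predecessors()
    indeg = {i: len(p) for i, p in preds.items()}
    succs = h.successors()
    stack = sorted(i for i, d in indeg.items() if d == 0)
    out = []
    while stack:
        u = stack.pop()
        out.append(u)
        for v in succs[u]:
            indeg[v] -= 1
            if indeg[v] == 0:
                stack.append(v)
    if len(out) != h.n_nodes:
        raise ValidationError("diagram contains a cycle")
    return out


def path_histogram(
    h: HasseDiagram, max_paths: int | None = DEFAULT_MAX_PATHS
) -> PathHistogram:
    """Exact per-length count of bottom-to-top paths by dynamic
    programming over the DAG; refuses pasts of more than *max_paths*
    total paths when a guard is given."""
    bottom, top = h.bottom(), h.top()
    succs = h.successors()
    # per node: dict length -> number of paths from bottom
    table: dict[int, dict[int, int]] = {n.node_id: {} for n in h.nodes}
    table[bottom.node_id] = {0: 1}
    for u in _topo_order(h):
        for length, cnt in table[u].items():
            for v in succs[u]:
                table[v][length + 1] = table[v].get(length + 1, 0) + cnt
    counts = dict(sorted(table[top.node_id].items()))
    hist = PathHistogram(counts)
    if max_paths is not None and hist.total_paths > max_paths:
        raise CapacityError(
            f"{hist.total_paths} bottom-to-top paths exceed the guard of "
            f"{max_paths}"
        )
    return hist


def enumerate_paths(
    h: HasseDiagram, max_paths: int = DEFAULT_MAX_PATHS
) -> list[tuple[int, ...]]:
    """Explicit DFS enumeration of bottom-to-top paths (node-id tuples);
    aborts with a capacity error past *max_paths*."""
    bottom, top = h.bottom(), h.top()
    succs = h.successors()
    out: list[tuple[int, ...]] = []
    stack = [(bottom.node_id, (bottom.node_id,))]
    while stack:
        u, path = stack.pop()
        if u == top.node_id:
            out.append(path)
            if len(out) > max_paths:
                raise CapacityError(
                    f"path enumeration exceeded the guard of {max_paths}"
                )
            continue
        for v in sorted(succs[u], reverse=True):
            stack.append((v, path + (v,)))
    return out


def ego_view(h: HasseDiagram, node_id: int, table=None) -> HasseDiagram:
    """Sub-diagram around a focal node: the node itself plus every
    measurement node whose set is a proper subset or superset of it,
    with covering edges recomputed inside the selection.  Node ids and
    annotations carry over from *h*."""
    focal = h.node(node_id)
    fm = focal.taxa.mask
    keep = [focal]
    for n in h.nodes:
        if n.node_id == node_id or not n.is_measurement:
            continue
        m = n.taxa.mask
        if m != fm and (m & fm == m or m & fm == fm):
            keep.append(n)
    keep.sort(key=lambda n: n.node_id)
    masks = [n.taxa.mask for n in keep]
    edges = [
        (keep[i].node_id, keep[j].node_id) for i, j in covering_edges(masks)
    ]
    return HasseDiagram(tuple(keep), tuple(sorted(edges)))
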