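"""Chemical organization theory on explicit reaction networks.

A reaction network is a set of species together with stoichiometric
reactions.  A set of species is *closed* when no reaction that can run
inside the set (all reactants present; inflows always can) produces a
species outside it, and *self-maintaining* when every member species has
at least one active reaction that net-produces it.  A set with both
properties is an *organization*: under replicator-style kinetics —
species arise only by inflow or (assisted) self-replication and all
species decay — only organizations can persist in the long run.

The self-maintenance test used here is the simplified replicator form
(an active net-producing reaction per member); the general flux-vector
formulation of the theory is deliberately not implemented.  Decay
reactions (``x ->``) never count against self-maintenance: they consume
at any rate but persistence is decided by the existence of production.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .errors import CapacityError, ValidationError
from .taxa import TaxaSet, TaxaUniverse

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "OrganizationSet",
    "OrganizationLattice",
    "is_closed",
    "is_self_maintaining",
    "closure_of",
    "enumerate_organizations",
    "organization_hasse",
]


@dataclass(frozen=True)
class Reaction:
    """One stoichiometric reaction; empty reactants = inflow, empty
    products = decay/outflow."""

    reactants: Mapping[str, int]
    products: Mapping[str, int]

    def __post_init__(self):
        object.__setattr__(self, "reactants", dict(self.reactants))
        object.__setattr__(self, "products", dict(self.products))
        if not self.reactants and not self.products:
            raise ValidationError("reaction needs at least one species")
        for side in (self.reactants, self.products):
            for sp, k in side.items():
                if int(k) < 1:
                    raise ValidationError(
                        f"stoichiometric coefficient for {sp!r} must be >= 1"
                    )

    @property
    def is_inflow(self) -> bool:
        return not self.reactants

    @property
    def is_outflow(self) -> bool:
        return not self.products

    def net_produces(self, species: str) -> bool:
        """True if the reaction increases the count of *species*."""
        return self.products.get(species, 0) > self.reactants.get(species, 0)

    def __str__(self) -> str:
        def side(d: Mapping[str, int]) -> str:
            return " + ".join(
                (f"{k} {sp}" if k > 1 else sp) for sp, k in d.items()
            )

        return f"{side(self.reactants)} -> {side(self.products)}".strip()


class ReactionNetwork:
    """Species roster plus reactions; species order is first appearance."""

    def __init__(self, species: Sequence[str], reactions: Iterable[Reaction]):
        self.species = tuple(species)
        self.reactions = tuple(reactions)
        if len(set(self.species)) != len(self.species):
            raise ValidationError("species names must be unique")
        known = set(self.species)
        for r in self.reactions:
            for sp in (*r.reactants, *r.products):
                if sp not in known:
                    raise ValidationError(
                        f"reaction {r} references undeclared species {sp!r}"
                    )
        self._universe: TaxaUniverse | None = None
        # precomputed bitmasks for the set algebra
        idx = {sp: i for i, sp in enumerate(self.species)}
        self._rxn_masks = []
        for r in self.reactions:
            rmask = sum(1 << idx[sp] for sp in r.reactants)
            pmask = sum(1 << idx[sp] for sp in r.products)
            net = sum(1 << idx[sp] for sp in set(r.products) if r.net_produces(sp))
            self._rxn_masks.append((rmask, pmask, net))

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def universe(self) -> TaxaUniverse:
        if self._universe is None:
            if not self.species:
                raise ValidationError("empty network has no species universe")
            self._universe = TaxaUniverse(self.species)
        return self._universe

    def set_of(self, members: Iterable[str | int]) -> TaxaSet:
        return self.universe.set_of(members)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ReactionNetwork)
            and self.species == other.species
            and self.reactions == other.reactions
        )

    def __repr__(self) -> str:
        return (
            f"ReactionNetwork({len(self.species)} species, "
            f"{len(self.reactions)} reactions)"
        )

    # -- mask-level primitives (used by the public predicates) ------------

    def _as_mask(self, s: TaxaSet | Iterable[str | int]) -> int:
        if isinstance(s, TaxaSet):
            if s.universe != self.universe:
                raise ValidationError(
                    "taxa set is defined over a different species roster"
                )
            return s.mask
        return self.set_of(s).mask

    def _closed_mask(self, mask: int) -> bool:
        for rmask, pmask, _ in self._rxn_masks:
            if rmask & mask == rmask and pmask & mask != pmask:
                return False
        return True

    def _self_maintaining_mask(self, mask: int) -> bool:
        producible = 0
        for rmask, _, net in self._rxn_masks:
            if rmask & mask == rmask:
                producible |= net
        return mask & producible == mask

    def _closure_mask(self, mask: int) -> int:
        while True:
            new = mask
            for rmask, pmask, _ in self._rxn_masks:
                if rmask & new == rmask:
                    new |= pmask
            if new == mask:
                return mask
            mask = new


def is_closed(s: TaxaSet | Iterable[str | int], net: ReactionNetwork) -> bool:
    """No reaction active on *s* produces a species outside *s*."""
    return net._closed_mask(net._as_mask(s))


def is_self_maintaining(
    s: TaxaSet | Iterable[str | int], net: ReactionNetwork
) -> bool:
    """Every member of *s* has an active reaction net-producing it.

    The empty set is vacuously self-maintaining.
    """
    return net._self_maintaining_mask(net._as_mask(s))


def closure_of(s: TaxaSet | Iterable[str | int], net: ReactionNetwork) -> TaxaSet:
    """Smallest closed superset of *s* (fixpoint of adding products of
    active reactions); extensive, monotone and idempotent."""
    return TaxaSet(net.universe, net._closure_mask(net._as_mask(s)))


@dataclass(frozen=True)
class OrganizationSet:
    """A species set with its closure/self-maintenance verdicts."""

    members: TaxaSet
    is_closed: bool
    is_self_maintaining: bool

    @property
    def is_organization(self) -> bool:
        return self.is_closed and self.is_self_maintaining


def enumerate_organizations(
    net: ReactionNetwork, max_species: int = 20
) -> list[OrganizationSet]:
    """All organizations of *net* by exhaustive scan of the 2^n subsets.

    Results are ordered by set size, then lexicographically on
    membership, so output is reproducible bit-exact.  Networks beyond
    *max_species* species are refused (the scan is exponential).
    """
    n = net.n_species
    if n > max_species:
        raise CapacityError(
            f"network has {n} species; exhaustive enumeration is limited to "
            f"{max_species} (raise max_species explicitly to override)"
        )
    out = []
    for mask in range(1 << n):
        if net._closed_mask(mask) and net._self_maintaining_mask(mask):
            out.append(
                OrganizationSet(
                    TaxaSet(net.universe, mask),
                    is_closed=True,
                    is_self_maintaining=True,
                )
            )
    out.sort(key=lambda o: o.members.sort_key())
    return out


@dataclass(frozen=True)
class OrganizationLattice:
    """Organizations plus the covering edges of their subset order."""

    organizations: tuple[OrganizationSet, ...]
    cover_edges: tuple[tuple[int, int], ...] = field(default_factory=tuple)


def organization_hasse(orgs: Sequence[OrganizationSet]) -> OrganizationLattice:
    """Hasse diagram (covering relation) of the subset order on *orgs*.

    An edge (i, j) means orgs[i] < orgs[j] with no organization strictly
    between — the transitive reduction of the subset DAG.
    """
    masks = [o.members.mask for o in orgs]
    if len(set(masks)) != len(masks):
        raise ValidationError("organization sets must be distinct")
    edges = []
    for i, j in combinations(range(len(orgs)), 2):
        for u, v in ((i, j), (j, i)):
            mu, mv = masks[u], masks[v]
            if mu != mv and mu & mv == mu:  # u proper subset of v
                if not any(
                    mw != mu and mw != mv and mu & mw == mu and mw & mv == mw
                    for mw in masks
                ):
                    edges.append((u, v))
    edges.sort()
    return OrganizationLattice(tuple(orgs), tuple(edges))
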