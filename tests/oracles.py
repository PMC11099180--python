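"""Independent brute-force oracles used to cross-check the package.

Everything here works on plain Python sets/frozensets and itertools and
deliberately avoids the package's own bitmask engines, so that the two
routes stay independent.
"""

from itertools import combinations

import numpy as np


# -- chemical organization theory ------------------------------------------


def brute_is_closed(members: frozenset, reactions) -> bool:
    """reactions: list of (reactants dict, products dict)."""
    for reactants, products in reactions:
        if set(reactants) <= members and not set(products) <= members:
            return False
    return True


def brute_is_self_maintaining(members: frozenset, reactions) -> bool:
    for x in members:
        ok = False
        for reactants, products in reactions:
            if set(reactants) <= members and products.get(x, 0) > reactants.get(x, 0):
                ok = True
                break
        if not ok:
            return False
    return True


def brute_organizations(species, reactions):
    """All closed + self-maintaining subsets, by explicit powerset scan."""
    out = []
    species = list(species)
    for r in range(len(species) + 1):
        for combo in combinations(species, r):
            s = frozenset(combo)
            if brute_is_closed(s, reactions) and brute_is_self_maintaining(
                s, reactions
            ):
                out.append(s)
    return out


def random_replicator_network(rng: np.random.Generator, n_species: int):
    """Random inhibition-free replicator system: every species is either
    an inflow, a self-replicator, or an assisted replicator; every
    species decays.  Returns (species, reactions-as-dict-pairs, text)."""
    species = [chr(ord("a") + i) for i in range(n_species)]
    reactions = []
    lines = []
    for i, sp in enumerate(species):
        kind = rng.integers(0, 3)
        if kind == 0:  # inflow
            reactions.append(({}, {sp: 1}))
            lines.append(f"-> {sp}")
        elif kind == 1:  # self-replication
            reactions.append(({sp: 1}, {sp: 2}))
            lines.append(f"{sp} -> 2 {sp}")
        else:  # replication assisted by other species
            n_help = int(rng.integers(1, min(3, n_species)))
            helpers = [
                species[j]
                for j in rng.choice(
                    [j for j in range(n_species) if j != i],
                    size=min(n_help, n_species - 1),
                    replace=False,
                )
            ]
            reactants = {h: 1 for h in helpers}
            reactants[sp] = 1
            products = {h: 1 for h in helpers}
            products[sp] = 2
            reactions.append((reactants, products))
            lines.append(
                " + ".join(helpers + [sp])
                + " -> "
                + " + ".join(helpers + [f"2 {sp}"])
            )
        reactions.append(({sp: 1}, {}))
        lines.append(f"{sp} ->")
    return species, reactions, "\n".join(lines)


# -- subset order ----------------------------------------------------------


def brute_subset_pairs(sets):
    """sets: list of frozensets (distinct)."""
    return [
        (i, j)
        for i in range(len(sets))
        for j in range(len(sets))
        if i != j and sets[i] < sets[j]
    ]


def brute_cover_edges(sets):
    """Covering relation on distinct frozensets (indices)."""
    out = []
    for i, u in enumerate(sets):
        for j, v in enumerate(sets):
            if u < v and not any(u < w < v for w in sets):
                out.append((i, j))
    return sorted(out)


def brute_paths(edges, bottom, top):
    """All bottom->top paths in a DAG given edge list; returns lengths."""
    succ = {}
    for u, v in edges:
        succ.setdefault(u, []).append(v)
    lengths = []

    def walk(u, depth):
        if u == top:
            lengths.append(depth)
            return
        for v in succ.get(u, []):
            walk(v, depth + 1)

    walk(bottom, 0)
    return sorted(lengths)


# -- formal concept analysis -----------------------------------------------


def brute_intents(measurements):
    """All intersections of all non-empty subsets of the measurements
    (frozensets); equals the set of concept intents of the context."""
    out = set()
    ms = list(measurements)
    for r in range(1, len(ms) + 1):
        for combo in combinations(range(len(ms)), r):
            inter = set(ms[combo[0]])
            for k in combo[1:]:
                inter &= ms[k]
            out.add(frozenset(inter))
    return out


def brute_concepts(samples):
    """samples: dict sample_id -> frozenset of taxa.  Returns the set of
    (extent frozenset, intent frozenset) Galois fixpoints with non-empty
    extent."""
    out = set()
    ids = list(samples)
    for r in range(1, len(ids) + 1):
        for combo in combinations(ids, r):
            intent = set(samples[combo[0]])
            for k in combo[1:]:
                intent &= samples[k]
            extent = frozenset(
                sid for sid in ids if set(samples[sid]) >= intent
            )
            # Galois closure: intent of the full extent
            closed_intent = set(samples[next(iter(extent))])
            for sid in extent:
                closed_intent &= samples[sid]
            out.add((extent, frozenset(closed_intent)))
    return out


def brute_additional(measurements):
    """Additional organizations of a family of frozensets, from the full
    intent enumeration."""
    ms = list(dict.fromkeys(measurements))
    out = []
    for s in brute_intents(ms):
        if s in ms:
            continue
        sup = [m for m in ms if m >= s]
        sub = [m for m in ms if m <= s]
        if len(sup) < 2 or len(sub) < 2:
            continue
        inter = set(sup[0])
        for m in sup[1:]:
            inter &= m
        union = set()
        for m in sub:
            union |= m
        if frozenset(inter) == s and frozenset(union) == s:
            out.append(s)
    return sorted(out, key=lambda s: (len(s), sorted(s)))
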