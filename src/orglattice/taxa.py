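"""Taxa universes and taxa sets.

A :class:`TaxaUniverse` fixes an ordered roster of taxon labels; the
position of a label is its abundance rank (rank 0 = most abundant, the
usual convention for phylum tables sorted by abundance).  A
:class:`TaxaSet` is an immutable subset of one universe, stored as an
integer bitmask keyed by rank, which makes the heavy set algebra of the
lattice computations (millions of intersections) cheap.

Set semantics are value semantics: two TaxaSets over universes with the
same label roster compare equal iff they contain the same members.
"""

from __future__ import annotations

from typing import Iterable, Iterator

from .errors import ValidationError

__all__ = ["TaxaUniverse", "TaxaSet"]


class TaxaUniverse:
    """Ordered roster of taxon labels; position = abundance rank."""

    __slots__ = ("labels", "_index", "_hash")

    def __init__(self, labels: Iterable[str]):
        labels = tuple(str(x) for x in labels)
        if len(labels) < 1:
            raise ValidationError("a taxa universe needs at least one taxon")
        if any(not lab for lab in labels):
            raise ValidationError("taxon labels must be non-empty strings")
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValidationError(f"duplicate taxon labels: {dupes}")
        self.labels = labels
        self._index = {lab: i for i, lab in enumerate(labels)}
        self._hash = hash(labels)

    @property
    def size(self) -> int:
        return len(self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise ValidationError(f"unknown taxon label: {label!r}") from None

    def __contains__(self, label: object) -> bool:
        return label in self._index

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TaxaUniverse) and self.labels == other.labels

    def __hash__(self) -> int:
        return self._hash

    def __repr__(self) -> str:
        return f"TaxaUniverse({len(self.labels)} taxa)"

    # -- set constructors -------------------------------------------------

    def empty(self) -> "TaxaSet":
        return TaxaSet(self, 0)

    def full(self) -> "TaxaSet":
        return TaxaSet(self, (1 << len(self.labels)) - 1)

    def set_of(self, members: Iterable[str | int]) -> "TaxaSet":
        """Build a TaxaSet from labels and/or rank indices."""
        mask = 0
        for m in members:
            if isinstance(m, str):
                i = self.index(m)
            else:
                i = int(m)
                if not 0 <= i < len(self.labels):
                    raise ValidationError(
                        f"taxon index {i} out of range for universe of "
                        f"size {len(self.labels)}"
                    )
            mask |= 1 << i
        return TaxaSet(self, mask)


class TaxaSet:
    """Immutable subset of a :class:`TaxaUniverse` (bitmask by rank)."""

    __slots__ = ("universe", "mask")

    def __init__(self, universe: TaxaUniverse, mask: int):
        if mask < 0 or mask >> len(universe.labels):
            raise ValidationError("membership mask exceeds universe size")
        object.__setattr__(self, "universe", universe)
        object.__setattr__(self, "mask", mask)

    def __setattr__(self, *a):  # pragma: no cover - immutability guard
        raise AttributeError("TaxaSet is immutable")

    # -- inspection --------------------------------------------------------

    def indices(self) -> tuple[int, ...]:
        m, out = self.mask, []
        while m:
            low = m & -m
            out.append(low.bit_length() - 1)
            m ^= low
        return tuple(out)

    def labels(self) -> tuple[str, ...]:
        ulab = self.universe.labels
        return tuple(ulab[i] for i in self.indices())

    def __iter__(self) -> Iterator[int]:
        return iter(self.indices())

    def __len__(self) -> int:
        return self.mask.bit_count()

    def __bool__(self) -> bool:
        return self.mask != 0

    def __contains__(self, item: str | int) -> bool:
        i = self.universe.index(item) if isinstance(item, str) else int(item)
        return bool(self.mask >> i & 1)

    # -- algebra -----------------------------------------------------------

    def _coerce(self, other: "TaxaSet") -> int:
        if not isinstance(other, TaxaSet) or other.universe != self.universe:
            raise ValidationError("TaxaSet operands must share a universe")
        return other.mask

    def __and__(self, other: "TaxaSet") -> "TaxaSet":
        return TaxaSet(self.universe, self.mask & self._coerce(other))

    def __or__(self, other: "TaxaSet") -> "TaxaSet":
        return TaxaSet(self.universe, self.mask | self._coerce(other))

    def __sub__(self, other: "TaxaSet") -> "TaxaSet":
        return TaxaSet(self.universe, self.mask & ~self._coerce(other))

    def issubset(self, other: "TaxaSet") -> bool:
        m = self._coerce(other)
        return self.mask & m == self.mask

    def __le__(self, other: "TaxaSet") -> bool:
        return self.issubset(other)

    def __lt__(self, other: "TaxaSet") -> bool:
        m = self._coerce(other)
        return self.mask != m and self.mask & m == self.mask

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, TaxaSet)
            and self.mask == other.mask
            and self.universe == other.universe
        )

    def __hash__(self) -> int:
        return hash((self.mask, self.universe))

    def sort_key(self) -> tuple[int, tuple[int, ...]]:
        """Deterministic ordering key: (size, lexicographic membership)."""
        return (self.mask.bit_count(), self.indices())

    def __repr__(self) -> str:
        labs = self.labels()
        body = ",".join(labs[:8]) + ("..." if len(labs) > 8 else "")
        return f"TaxaSet({{{body}}})"
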