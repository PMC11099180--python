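"""Readers and writers: community matrices, reaction networks, results.

The matrix contract is delimited text (TSV/CSV) with taxa in rows by
default: first column = taxon label, header = sample ids.  Sample ids of
the form ``WELL:TIME`` are split into a well label and an integer time
point (months); anything else is kept as an opaque id with well ``NA``
and the column ordinal as time.  Presence means value strictly greater
than the binarization threshold (default 0 — suitable for tables that
are already 0/1).

Reaction networks use a one-reaction-per-line text format::

    # comment
    -> a          # inflow
    b -> 2 b      # replication
    c + a -> a + 2 c
    a ->          # decay

Result objects (diagrams, concept lists, curves, summaries) serialize
to JSON with taxon *labels*, never rank indices, and round-trip.
"""

from __future__ import annotations

import json
import os
import re
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .concepts import Concept
from .cot import Reaction, ReactionNetwork
from .errors import InputOutputError, ParseError, ValidationError
from .lattice import HasseDiagram, LatticeNode
from .taxa import TaxaSet, TaxaUniverse

__all__ = [
    "SampleRecord",
    "MeasurementTable",
    "read_measurement_matrix",
    "write_measurement_matrix",
    "parse_reaction_network",
    "format_reaction_network",
    "read_reaction_network",
    "write_results",
    "read_hasse_json",
    "read_concepts_json",
]

_SAMPLE_ID_RE = re.compile(r"^(?P<well>.+):(?P<time>\d+)$")


@dataclass(frozen=True)
class SampleRecord:
    """One measurement: a well/time-labelled binarized taxa set."""

    sample_id: str
    well: str
    time_point: int
    taxa: TaxaSet


class MeasurementTable:
    """All samples of a study over one shared taxa universe."""

    def __init__(self, universe: TaxaUniverse, samples: Sequence[SampleRecord]):
        samples = tuple(samples)
        if not samples:
            raise ValidationError("a measurement table needs >= 1 sample")
        for rec in samples:
            if rec.taxa.universe != universe:
                raise ValidationError(
                    f"sample {rec.sample_id!r} uses a different taxa universe"
                )
        keys = [(rec.well, rec.time_point) for rec in samples]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValidationError(f"duplicate (well, time_point) pairs: {dupes}")
        self.universe = universe
        self.samples = samples

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def taxa_sets(self) -> list[TaxaSet]:
        return [rec.taxa for rec in self.samples]

    def wells(self) -> list[str]:
        out: dict[str, None] = {}
        for rec in self.samples:
            out.setdefault(rec.well, None)
        return list(out)

    def sample(self, sample_id: str) -> SampleRecord:
        for rec in self.samples:
            if rec.sample_id == sample_id:
                return rec
        raise ValidationError(f"no sample with id {sample_id!r}")

    def occurrence_frequencies(self) -> list[float]:
        """Per-taxon fraction of samples the taxon is present in."""
        n = len(self.samples)
        return [
            sum(1 for rec in self.samples if rec.taxa.mask >> i & 1) / n
            for i in range(self.universe.size)
        ]

    def to_dataframe(self) -> pd.DataFrame:
        """Binary taxa-by-sample DataFrame (rows = taxa, 0/1 ints)."""
        data = {
            rec.sample_id: [
                int(rec.taxa.mask >> i & 1) for i in range(self.universe.size)
            ]
            for rec in self.samples
        }
        return pd.DataFrame(data, index=list(self.universe.labels))

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, MeasurementTable)
            and self.universe == other.universe
            and self.samples == other.samples
        )


def _parse_sample_id(label: str, ordinal: int) -> tuple[str, int]:
    m = _SAMPLE_ID_RE.match(label)
    if m:
        return m.group("well"), int(m.group("time"))
    return "NA", ordinal


def read_measurement_matrix(
    path: str | os.PathLike,
    orientation: str = "taxa_rows",
    binarize_threshold: float = 0.0,
) -> MeasurementTable:
    """Read a delimited abundance/presence matrix and binarize it.

    A taxon is present in a sample iff its value is strictly greater
    than *binarize_threshold*.  Universe order is the file's row order
    (treated as abundance rank).  ``orientation="samples_rows"``
    transposes after reading.
    """
    if orientation not in ("taxa_rows", "samples_rows"):
        raise ValidationError(f"unknown orientation: {orientation!r}")
    if binarize_threshold < 0:
        raise ValidationError("binarize_threshold must be >= 0")
    try:
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    except OSError as e:
        raise InputOutputError(f"cannot read {path}: {e}") from e
    except pd.errors.ParserError as e:
        raise ParseError(f"malformed table in {path}: {e}") from e
    if orientation == "samples_rows":
        df = df.T
    taxa_labels = [str(x) for x in df.index]
    if len(set(taxa_labels)) != len(taxa_labels):
        dupes = sorted({x for x in taxa_labels if taxa_labels.count(x) > 1})
        raise ValidationError(f"duplicate taxon labels: {dupes}")
    try:
        values = df.astype(float)
    except (TypeError, ValueError) as e:
        raise ParseError(f"non-numeric value in {path}: {e}") from e
    if values.isna().any().any():
        row = values.index[values.isna().any(axis=1)][0]
        raise ParseError(f"missing/unparseable value in row {row!r} of {path}")
    if (values < 0).any().any():
        row = values.index[(values < 0).any(axis=1)][0]
        raise ValidationError(f"negative abundance in row {row!r} of {path}")

    universe = TaxaUniverse(taxa_labels)
    samples = []
    for ordinal, col in enumerate(values.columns):
        mask = 0
        for i, v in enumerate(values[col].to_numpy()):
            if v > binarize_threshold:
                mask |= 1 << i
        well, time_point = _parse_sample_id(str(col), ordinal)
        samples.append(
            SampleRecord(str(col), well, time_point, TaxaSet(universe, mask))
        )
    return MeasurementTable(universe, samples)


def write_measurement_matrix(table: MeasurementTable, path: str | os.PathLike):
    """Write the binary matrix as TSV (taxa rows, 0/1)."""
    try:
        _atomic_write(path, table.to_dataframe().to_csv(sep="\t", index_label="taxon"))
    except OSError as e:
        raise InputOutputError(f"cannot write {path}: {e}") from e


# ---------------------------------------------------------------------------
# reaction networks
# ---------------------------------------------------------------------------


def _parse_side(text: str, lineno: int) -> dict[str, int]:
    out: dict[str, int] = {}
    text = text.strip()
    if not text:
        return out
    for term in text.split("+"):
        parts = term.split()
        if len(parts) == 1:
            k, name = 1, parts[0]
        elif len(parts) == 2:
            try:
                k = int(parts[0])
            except ValueError:
                raise ParseError(
                    f"line {lineno}: bad coefficient {parts[0]!r}"
                ) from None
            name = parts[1]
        else:
            raise ParseError(f"line {lineno}: cannot parse term {term.strip()!r}")
        if k < 1:
            raise ParseError(f"line {lineno}: coefficient must be >= 1")
        if not name or "->" in name:
            raise ParseError(f"line {lineno}: bad species name {name!r}")
        out[name] = out.get(name, 0) + k
    return out


def parse_reaction_network(text: str) -> ReactionNetwork:
    """Parse the one-reaction-per-line format; ``#`` starts a comment.

    Species roster order = first appearance.  Either side of ``->`` may
    be empty (inflow / decay)."""
    species: dict[str, None] = {}
    reactions = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.count("->") != 1:
            raise ParseError(f"line {lineno}: expected exactly one '->'")
        lhs, rhs = line.split("->")
        reactants = _parse_side(lhs, lineno)
        products = _parse_side(rhs, lineno)
        if not reactants and not products:
            raise ParseError(f"line {lineno}: reaction has no species")
        for name in (*reactants, *products):
            species.setdefault(name, None)
        reactions.append(Reaction(reactants, products))
    return ReactionNetwork(list(species), reactions)


def format_reaction_network(net: ReactionNetwork) -> str:
    """Canonical text form; ``parse_reaction_network`` round-trips it."""
    return "\n".join(str(r) for r in net.reactions) + ("\n" if net.reactions else "")


def read_reaction_network(path: str | os.PathLike) -> ReactionNetwork:
    try:
        with open(path) as fh:
            return parse_reaction_network(fh.read())
    except OSError as e:
        raise InputOutputError(f"cannot read {path}: {e}") from e


# ---------------------------------------------------------------------------
# result serialization
# ---------------------------------------------------------------------------


def _taxa_json(s: TaxaSet) -> list[str]:
    return list(s.labels())


def _node_json(n: LatticeNode) -> dict:
    return {
        "id": n.node_id,
        "taxa": _taxa_json(n.taxa),
        "kind": n.kind,
        "support": list(n.support),
        "introduced": _taxa_json(n.introduced) if n.introduced is not None else [],
        "n_supersets": n.n_supersets,
        "n_subsets": n.n_subsets,
        "is_measurement": n.is_measurement,
        "is_self_maintaining": n.is_self_maintaining,
    }


def to_jsonable(obj) -> dict:
    """Convert a result object to a JSON-ready dict (labels, not ranks)."""
    if isinstance(obj, HasseDiagram):
        universe = obj.nodes[0].taxa.universe if obj.nodes else None
        return {
            "type": "hasse_diagram",
            "universe": list(universe.labels) if universe else [],
            "nodes": [_node_json(n) for n in obj.nodes],
            "edges": [list(e) for e in obj.edges],
        }
    if isinstance(obj, dict):
        return obj
    if isinstance(obj, (list, tuple)):
        items = list(obj)
        if all(isinstance(x, TaxaSet) for x in items) and items:
            return {
                "type": "taxa_sets",
                "universe": list(items[0].universe.labels),
                "sets": [_taxa_json(s) for s in items],
            }
        if all(isinstance(x, Concept) for x in items) and items:
            return {
                "type": "concepts",
                "universe": list(items[0].intent.universe.labels),
                "concepts": [
                    {
                        "extent": list(c.extent),
                        "intent": _taxa_json(c.intent),
                        "support": c.support,
                    }
                    for c in items
                ],
            }
    if hasattr(obj, "to_jsonable"):
        return obj.to_jsonable()
    raise ValidationError(f"cannot serialize object of type {type(obj).__name__}")


def _hasse_tsv(d: dict) -> str:
    rows = ["id\tkind\tn_taxa\ttaxa\tintroduced\tn_supersets\tn_subsets\t"
            "support\tis_measurement\tis_self_maintaining"]
    for n in d["nodes"]:
        rows.append(
            "\t".join(
                [
                    str(n["id"]),
                    n["kind"],
                    str(len(n["taxa"])),
                    ",".join(n["taxa"]),
                    ",".join(n["introduced"]),
                    str(n["n_supersets"]),
                    str(n["n_subsets"]),
                    ",".join(n["support"]),
                    str(int(n["is_measurement"])),
                    str(int(n["is_self_maintaining"])),
                ]
            )
        )
    return "\n".join(rows) + "\n"


def write_results(obj, path: str | os.PathLike, format: str = "json"):
    """Serialize a result object to *path* as JSON or TSV."""
    if format not in ("json", "tsv"):
        raise ValidationError(f"unknown format: {format!r}")
    d = to_jsonable(obj)
    if format == "json":
        text = json.dumps(d, indent=1, sort_keys=False) + "\n"
    else:
        if d.get("type") == "hasse_diagram":
            text = _hasse_tsv(d)
        elif d.get("type") == "taxa_sets":
            text = "\n".join(",".join(s) for s in d["sets"]) + "\n"
        elif "rows" in d:  # generic tabular payloads (curves, summaries)
            header = d["columns"]
            lines = ["\t".join(header)]
            lines += ["\t".join(str(x) for x in row) for row in d["rows"]]
            text = "\n".join(lines) + "\n"
        else:
            raise ValidationError(
                f"no TSV form for result type {d.get('type')!r}"
            )
    try:
        _atomic_write(path, text)
    except OSError as e:
        raise InputOutputError(f"cannot write {path}: {e}") from e


def _atomic_write(path: str | os.PathLike, text: str):
    tmp = f"{path}.tmp"
    with open(tmp, "w") as fh:
        fh.write(text)
    os.replace(tmp, path)


def read_hasse_json(path: str | os.PathLike) -> HasseDiagram:
    """Inverse of ``write_results`` for Hasse diagrams."""
    try:
        with open(path) as fh:
            d = json.load(fh)
    except OSError as e:
        raise InputOutputError(f"cannot read {path}: {e}") from e
    if d.get("type") != "hasse_diagram":
        raise ValidationError(f"{path} does not hold a hasse_diagram")
    universe = TaxaUniverse(d["universe"])
    nodes = tuple(
        LatticeNode(
            node_id=n["id"],
            taxa=universe.set_of(n["taxa"]),
            kind=n["kind"],
            support=tuple(n["support"]),
            introduced=universe.set_of(n["introduced"]),
            n_supersets=n["n_supersets"],
            n_subsets=n["n_subsets"],
            is_measurement=n["is_measurement"],
            is_self_maintaining=n["is_self_maintaining"],
        )
        for n in d["nodes"]
    )
    return HasseDiagram(nodes, tuple(tuple(e) for e in d["edges"]))


def read_concepts_json(path: str | os.PathLike) -> list[Concept]:
    try:
        with open(path) as fh:
            d = json.load(fh)
    except OSError as e:
        raise InputOutputError(f"cannot read {path}: {e}") from e
    if d.get("type") != "concepts":
        raise ValidationError(f"{path} does not hold a concept list")
    universe = TaxaUniverse(d["universe"])
    return [
        Concept(tuple(c["extent"]), universe.set_of(c["intent"]))
        for c in d["concepts"]
    ]
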