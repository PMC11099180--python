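"""Graphviz DOT and GraphML emission for annotated Hasse diagrams.

Node schema follows the lattice-node convention of the analysis: first
label line = node id, taxa count and (n_supersets, n_subsets); second
line = the taxa the set introduces; below, one box per well listing the
time points of the supporting measurements.  A grey fill marks a
self-maintaining set, a colored border marks a measurement (border
color = its well).  Layout itself is left to Graphviz; GraphML export
is lossless and meant for downstream graph tooling.

Rendering is a pure function of diagram + style: identical inputs give
byte-identical output.
"""

from __future__ import annotations

import html
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx

from .errors import ValidationError
from .lattice import HasseDiagram, LatticeNode

__all__ = ["RenderStyle", "to_dot", "to_graphml"]

_DEFAULT_WELL_COLORS = {
    "H41": "blue",
    "H43": "gold",
    "H51": "green",
    "H52": "red",
}

_FALLBACK_COLORS = (
    "purple", "orange", "brown", "cyan", "magenta", "olive", "navy", "teal",
)


@dataclass(frozen=True)
class RenderStyle:
    """Color and label conventions for DOT emission."""

    well_colors: Mapping[str, str] = field(
        default_factory=lambda: dict(_DEFAULT_WELL_COLORS)
    )
    self_maintaining_fill: str = "grey90"
    max_label_taxa: int = 12
    strict_wells: bool = False  # error on wells without an assigned color


def _well_color(style: RenderStyle, well: str, extra: dict[str, str]) -> str:
    if well in style.well_colors:
        return style.well_colors[well]
    if style.strict_wells:
        raise ValidationError(f"no color assigned for well {well!r}")
    if well not in extra:
        extra[well] = _FALLBACK_COLORS[len(extra) % len(_FALLBACK_COLORS)]
    return extra[well]


def _support_by_well(node: LatticeNode, table) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    if table is None:
        for sid in node.support:
            well, _, time = sid.partition(":")
            out.setdefault(well, []).append(int(time) if time.isdigit() else -1)
        return out
    by_id = {rec.sample_id: rec for rec in table.samples}
    for sid in node.support:
        rec = by_id.get(sid)
        if rec is None:
            continue
        out.setdefault(rec.well, []).append(rec.time_point)
    return out


def _taxa_text(node: LatticeNode, style: RenderStyle) -> str:
    labs = node.introduced.labels() if node.introduced is not None else ()
    if len(labs) > style.max_label_taxa:
        labs = labs[: style.max_label_taxa] + ("...",)
    return ",".join(labs)


def _node_dot(node: LatticeNode, style: RenderStyle, table, extra) -> str:
    wells = _support_by_well(node, table)
    line1 = (
        f"{node.node_id}, {len(node.taxa)} "
        f"({node.n_supersets}, {node.n_subsets})"
    )
    line2 = f"[{_taxa_text(node, style)}]"
    cells = "".join(
        f'<TD BGCOLOR="{_well_color(style, w, extra)}">'
        f"{html.escape(','.join(str(t) for t in sorted(ts)))}</TD>"
        for w, ts in sorted(wells.items())
    )
    boxes = f"<TR>{cells}</TR>" if cells else ""
    label = (
        '<<TABLE BORDER="0" CELLBORDER="1" CELLSPACING="0">'
        f'<TR><TD COLSPAN="{max(1, len(wells))}">{html.escape(line1)}<BR/>'
        f"{html.escape(line2)}</TD></TR>{boxes}</TABLE>>"
    )
    fill = style.self_maintaining_fill if node.is_self_maintaining else "white"
    if node.is_measurement and wells:
        own = [
            w for w, ts in sorted(wells.items())
        ]  # border color: first supporting well
        border = _well_color(style, own[0], extra)
    else:
        border = "black"
    tooltip = html.escape(",".join(node.taxa.labels()))
    return (
        f'  n{node.node_id} [shape=box, style=filled, fillcolor="{fill}", '
        f'color="{border}", label={label}, tooltip="{tooltip}"];'
    )


def to_dot(h: HasseDiagram, style: RenderStyle | None = None, table=None) -> str:
    """Emit the annotated diagram as Graphviz DOT text (edges sub -> super,
    nodes ranked bottom-to-top by set size)."""
    style = style or RenderStyle()
    extra: dict[str, str] = {}
    lines = [
        "digraph hasse {",
        "  rankdir=BT;",
        "  node [fontsize=10];",
        '  label="node ids are deterministic (size, then lexicographic)";',
    ]
    for node in h.nodes:
        lines.append(_node_dot(node, style, table, extra))
    by_size: dict[int, list[int]] = {}
    for node in h.nodes:
        by_size.setdefault(len(node.taxa), []).append(node.node_id)
    for size in sorted(by_size):
        ids = " ".join(f"n{i};" for i in by_size[size])
        lines.append(f"  {{ rank=same; {ids} }}")
    for u, v in h.edges:
        lines.append(f"  n{u} -> n{v};")
    lines.append("}")
    return "\n".join(lines) + "\n"


def to_graphml(h: HasseDiagram) -> str:
    """Lossless structural export: every node attribute as a typed key."""
    g = nx.DiGraph()
    for n in h.nodes:
        g.add_node(
            n.node_id,
            kind=n.kind,
            taxa=",".join(n.taxa.labels()),
            introduced=",".join(
                n.introduced.labels() if n.introduced is not None else ()
            ),
            support=",".join(n.support),
            n_supersets=n.n_supersets,
            n_subsets=n.n_subsets,
            is_measurement=n.is_measurement,
            is_self_maintaining=n.is_self_maintaining,
        )
    for u, v in h.edges:
        g.add_edge(u, v)
    return "\n".join(nx.generate_graphml(g)) + "\n"
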