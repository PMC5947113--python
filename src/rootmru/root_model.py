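"""Root-system topology/geometry model and RSML 1.0 I/O.

A :class:`RootSystem` is a flat, ordered collection of :class:`RootAxis`
objects linked by parent references.  Axis *order* follows the field
convention for dicot root systems: order 1 is a basal "main" root (the
backbone of one mature root unit), order 2 a lateral root borne on a main
root, order 3 a secondary lateral borne on a lateral.  Geometry (polylines)
is optional — every downstream trait depends only on axis lengths and
insertion positions, so topology-only systems are first-class.

Skeletonization tools emit an undirected segment graph rather than ordered
axes; :func:`resolve_axes` converts such a graph into a ``RootSystem``
deterministically, electing the longest base-to-tip path of each basal
subtree as its main axis (the "longest root observed" convention used when
no primary root is morphologically distinguishable).

All lengths are centimetres, everywhere.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from lxml import etree

__all__ = [
    "RootAxis",
    "RootSystem",
    "SegmentGraph",
    "RootModelError",
    "axis_length",
    "resolve_axes",
    "read_rsml",
    "write_rsml",
]


class RootModelError(ValueError):
    """Invalid topology, geometry or RSML input."""


#: conversion factors to centimetres for RSML unit metadata
_UNIT_TO_CM = {
    "m": 100.0,
    "dm": 10.0,
    "cm": 1.0,
    "mm": 0.1,
    "um": 1e-4,
    "micrometer": 1e-4,
    "inch": 2.54,
}

_ARC_TOL = 1e-9  # cm; declared length must match polyline arc length


def axis_length(polyline: Sequence[Sequence[float]]) -> float:
    """Arc length (cm) of an ordered 2D polyline.

    Sum of Euclidean segment lengths; duplicated consecutive points
    contribute zero.  Requires at least two points.
    """
    if len(polyline) < 2:
        raise RootModelError("polyline needs >= 2 points")
    total = 0.0
    for (x0, y0), (x1, y1) in zip(polyline, polyline[1:]):
        total += math.hypot(x1 - x0, y1 - y0)
    return total


@dataclass
class RootAxis:
    """One root axis: a main root, lateral, or secondary lateral.

    Parameters
    ----------
    id : str
        Opaque identifier, unique within a system.
    order : int
        1 = basal/main, 2 = lateral, 3 = secondary lateral.
    length : float
        Axis length in cm, > 0.
    parent_id : str, optional
        Identifier of the bearing axis; ``None`` iff ``order == 1``.
    insertion_pos : float, optional
        Distance (cm) from the parent axis base (root-shoot junction end)
        to the branch point; ``None`` iff ``order == 1``.
    polyline : list of (x, y), optional
        Geometry in cm.  When present its arc length must equal ``length``.
    """

    id: str
    order: int
    length: float
    parent_id: Optional[str] = None
    insertion_pos: Optional[float] = None
    polyline: Optional[list[tuple[float, float]]] = None

    def __post_init__(self) -> None:
        if self.order < 1:
            raise RootModelError(f"axis {self.id!r}: order must be >= 1")
        if not self.length > 0:
            raise RootModelError(f"axis {self.id!r}: length must be > 0")
        if (self.parent_id is None) != (self.order == 1):
            raise RootModelError(
                f"axis {self.id!r}: parent_id must be absent iff order == 1"
            )
        if (self.insertion_pos is None) != (self.order == 1):
            raise RootModelError(
                f"axis {self.id!r}: insertion_pos must be absent iff order == 1"
            )
        if self.polyline is not None:
            arc = axis_length(self.polyline)
            if abs(arc - self.length) > _ARC_TOL:
                raise RootModelError(
                    f"axis {self.id!r}: polyline arc length {arc} != length "
                    f"{self.length}"
                )


@dataclass
class RootSystem:
    """The root system of one plant: an ordered set of axes.

    Axis insertion order is preserved and meaningful — iteration order is
    the contract downstream accumulators rely on.
    """

    plant_id: str
    accession: str = "synthetic"
    axes: list[RootAxis] = field(default_factory=list)
    scale: float = 1.0  # cm per coordinate unit of the source geometry

    def __post_init__(self) -> None:
        self.validate()

    def axis(self, axis_id: str) -> RootAxis:
        for ax in self.axes:
            if ax.id == axis_id:
                return ax
        raise KeyError(axis_id)

    def validate(self) -> None:
        by_id: dict[str, RootAxis] = {}
        for ax in self.axes:
            if ax.id in by_id:
                raise RootModelError(f"duplicate axis id {ax.id!r}")
            by_id[ax.id] = ax
        for ax in self.axes:
            if ax.parent_id is None:
                continue
            parent = by_id.get(ax.parent_id)
            if parent is None:
                raise RootModelError(
                    f"axis {ax.id!r}: parent {ax.parent_id!r} does not exist"
                )
            if ax.order != parent.order + 1:
                raise RootModelError(
                    f"axis {ax.id!r}: order {ax.order} != parent order "
                    f"{parent.order} + 1"
                )
            if not (0.0 <= ax.insertion_pos <= parent.length):
                raise RootModelError(
                    f"axis {ax.id!r}: insertion_pos {ax.insertion_pos} outside "
                    f"[0, {parent.length}]"
                )
        # parent references are acyclic by the order constraint (strictly
        # increasing along any parent chain), so no explicit cycle walk.

    # -- plain-text serialization (fixtures, manifests) ------------------

    def to_dict(self) -> dict:
        return {
            "plant_id": self.plant_id,
            "accession": self.accession,
            "scale": self.scale,
            "axes": [
                {
                    "id": ax.id,
                    "order": ax.order,
                    "length": ax.length,
                    "parent_id": ax.parent_id,
                    "insertion_pos": ax.insertion_pos,
                    "polyline": ax.polyline,
                }
                for ax in self.axes
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RootSystem":
        axes = [
            RootAxis(
                id=a["id"],
                order=a["order"],
                length=a["length"],
                parent_id=a.get("parent_id"),
                insertion_pos=a.get("insertion_pos"),
                polyline=[tuple(p) for p in a["polyline"]]
                if a.get("polyline")
                else None,
            )
            for a in d["axes"]
        ]
        return cls(
            plant_id=d["plant_id"],
            accession=d.get("accession", "synthetic"),
            axes=axes,
            scale=d.get("scale", 1.0),
        )

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_json(cls, s: str) -> "RootSystem":
        return cls.from_dict(json.loads(s))


@dataclass
class SegmentGraph:
    """Undirected segment graph, the raw output form of skeletonizers.

    ``nodes`` maps node id to an (x, y) point in cm (coordinates may be
    ``None`` for topology-only graphs); ``edges`` are (u, v, length) with
    length > 0.  One designated ``base`` node marks the root-shoot junction.
    """

    nodes: dict[str, Optional[tuple[float, float]]]
    edges: list[tuple[str, str, float]]
    base: str

    def __post_init__(self) -> None:
        if self.base not in self.nodes:
            raise RootModelError(f"base node {self.base!r} not in graph")
        for u, v, w in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise RootModelError(f"edge ({u!r}, {v!r}) references unknown node")
            if not w > 0:
                raise RootModelError(f"edge ({u!r}, {v!r}) length must be > 0")


def resolve_axes(
    graph: SegmentGraph,
    base: Optional[str] = None,
    plant_id: str = "plant",
    accession: str = "synthetic",
) -> RootSystem:
    """Resolve an ambiguous segment graph into ordered axes.

    Each subtree hanging off the base node becomes one basal (order-1)
    axis whose path is the *heaviest* (maximum total length) base-to-tip
    path in that subtree; branches off the elected path become laterals
    recursively, with ``insertion_pos`` measured along the parent axis
    from its base.  Ties between equally heavy continuations are broken
    toward the lexicographically smaller next node id, which makes the
    output independent of edge ordering and stable across runs.

    Raises on disconnected graphs (listing unreachable nodes) and cycles.
    """
    base = graph.base if base is None else base
    adj: dict[str, list[tuple[str, float]]] = {n: [] for n in graph.nodes}
    for u, v, w in graph.edges:
        adj[u].append((v, w))
        adj[v].append((u, w))

    # connectivity + cycle check
    seen = {base}
    stack = [(base, None)]
    while stack:
        node, parent = stack.pop()
        for nxt, _ in adj[node]:
            if nxt == parent:
                continue
            if nxt in seen:
                raise RootModelError(f"cycle detected at node {nxt!r}")
            seen.add(nxt)
            stack.append((nxt, node))
    unreachable = sorted(set(graph.nodes) - seen)
    if unreachable:
        raise RootModelError(f"disconnected graph; unreachable nodes: {unreachable}")

    def tipdist(node: str, came_from: Optional[str]) -> float:
        """Longest distance from *node* to any tip, not backtracking."""
        best = 0.0
        for nxt, w in adj[node]:
            if nxt == came_from:
                continue
            best = max(best, w + tipdist(nxt, node))
        return best

    axes: list[RootAxis] = []
    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return f"ax{counter[0]}"

    def build_axis(
        start: str,
        first: str,
        order: int,
        parent_axis: Optional[str],
        insertion: Optional[float],
    ) -> None:
        axis_id = new_id()
        pos = 0.0
        branch_points: list[tuple[str, str, float]] = []  # (node, child, pos)
        poly: Optional[list[tuple[float, float]]] = (
            [graph.nodes[start]] if graph.nodes[start] is not None else None
        )
        cur, nxt = start, first
        while True:
            w = next(ww for (n, ww) in adj[cur] if n == nxt)
            pos += w
            if poly is not None and graph.nodes[nxt] is not None:
                poly.append(graph.nodes[nxt])
            else:
                poly = None
            children = [(n, ww) for (n, ww) in adj[nxt] if n != cur]
            if not children:
                break
            # heaviest continuation; tie -> lexicographically smaller node id
            main = min(
                children,
                key=lambda cw: (-(cw[1] + tipdist(cw[0], nxt)), cw[0]),
            )
            for child, _ in sorted(children):  # id order, not edge order
                if child != main[0]:
                    branch_points.append((nxt, child, pos))
            cur, nxt = nxt, main[0]
        # polyline arc length can disagree with summed edge weights when the
        # graph carries non-geometric weights; drop geometry in that case
        if poly is not None and abs(axis_length(poly) - pos) > _ARC_TOL:
            poly = None
        axes.append(
            RootAxis(
                id=axis_id,
                order=order,
                length=pos,
                parent_id=parent_axis,
                insertion_pos=insertion,
                polyline=poly,
            )
        )
        for node, child, bpos in branch_points:
            build_axis(node, child, order + 1, axis_id, bpos)

    # each base-incident edge starts one basal subtree, in id order
    for child, _ in sorted(adj[base]):
        build_axis(base, child, 1, None, None)

    return RootSystem(plant_id=plant_id, accession=accession, axes=axes)


# ---------------------------------------------------------------------------
# RSML 1.0 I/O
# ---------------------------------------------------------------------------


def _axis_to_element(ax: RootAxis, children: dict[str, list[RootAxis]]) -> etree._Element:
    el = etree.Element("root", ID=ax.id)
    props = etree.SubElement(el, "properties")
    etree.SubElement(props, "length", value=repr(ax.length))
    if ax.insertion_pos is not None:
        etree.SubElement(props, "insertion_pos", value=repr(ax.insertion_pos))
    if ax.polyline is not None:
        geom = etree.SubElement(el, "geometry")
        line = etree.SubElement(geom, "polyline")
        for x, y in ax.polyline:
            etree.SubElement(line, "point", x=repr(x), y=repr(y))
    for child in children.get(ax.id, []):
        el.append(_axis_to_element(child, children))
    return el


def write_rsml(systems: Iterable[RootSystem], path) -> None:
    """Write root systems to an RSML 1.0 file (unit metadata: cm)."""
    rsml = etree.Element("rsml")
    meta = etree.SubElement(rsml, "metadata")
    etree.SubElement(meta, "version").text = "1"
    etree.SubElement(meta, "unit").text = "cm"
    etree.SubElement(meta, "resolution").text = "1"
    etree.SubElement(meta, "software").text = "rootmru"
    scene = etree.SubElement(rsml, "scene")
    for system in systems:
        plant = etree.SubElement(
            scene, "plant", id=system.plant_id, label=system.accession
        )
        children: dict[str, list[RootAxis]] = {}
        for ax in system.axes:
            if ax.parent_id is not None:
                children.setdefault(ax.parent_id, []).append(ax)
        for ax in system.axes:
            if ax.order == 1:
                plant.append(_axis_to_element(ax, children))
    tree = etree.ElementTree(rsml)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)


def _prop(el: etree._Element, name: str) -> Optional[float]:
    props = el.find("properties")
    if props is None:
        return None
    p = props.find(name)
    if p is None:
        return None
    return float(p.get("value"))


def _read_axis(
    el: etree._Element,
    order: int,
    parent: Optional[RootAxis],
    factor: float,
    axes: list[RootAxis],
    counter: list[int],
) -> None:
    counter[0] += 1
    axis_id = el.get("ID") or el.get("id") or f"root{counter[0]}"
    explicit_parent = el.get("parent")
    if explicit_parent is not None:
        if parent is None or explicit_parent != parent.id:
            raise RootModelError(
                f"root element {axis_id!r}: declared parent {explicit_parent!r} "
                "does not exist in the enclosing topology"
            )
    poly = None
    line = el.find("geometry/polyline")
    if line is not None:
        poly = [
            (float(p.get("x")) * factor, float(p.get("y")) * factor)
            for p in line.findall("point")
        ]
    if poly is not None and len(poly) >= 2:
        length = axis_length(poly)
    else:
        poly = None
        declared = _prop(el, "length")
        if declared is None:
            raise RootModelError(
                f"root element {axis_id!r}: no polyline and no length property"
            )
        length = declared * factor
    insertion = None
    if parent is not None:
        ins = _prop(el, "insertion_pos")
        if ins is None:
            raise RootModelError(
                f"root element {axis_id!r}: nested root lacks insertion_pos"
            )
        insertion = ins * factor
    ax = RootAxis(
        id=axis_id,
        order=order,
        length=length,
        parent_id=parent.id if parent else None,
        insertion_pos=insertion,
        polyline=poly,
    )
    axes.append(ax)
    for sub in el.findall("root"):
        _read_axis(sub, order + 1, ax, factor, axes, counter)


def read_rsml(path) -> list[RootSystem]:
    """Read an RSML 1.0 file into a list of :class:`RootSystem`.

    Unit metadata is mandatory: files without a resolvable length unit are
    rejected rather than silently interpreted as pixels.
    """
    tree = etree.parse(str(path))
    rsml = tree.getroot()
    unit_el = rsml.find("metadata/unit")
    if unit_el is None or not (unit_el.text or "").strip():
        raise RootModelError("RSML file lacks unit metadata; refusing to guess")
    unit = unit_el.text.strip().lower()
    if unit not in _UNIT_TO_CM:
        raise RootModelError(
            f"RSML unit {unit!r} is not a physical length unit; refusing to guess"
        )
    res_el = rsml.find("metadata/resolution")
    resolution = float(res_el.text) if res_el is not None and res_el.text else 1.0
    if not resolution > 0:
        raise RootModelError("RSML resolution must be > 0")
    # resolution = coordinate units per physical unit
    factor = _UNIT_TO_CM[unit] / resolution

    systems = []
    for plant in rsml.findall("scene/plant"):
        axes: list[RootAxis] = []
        counter = [0]
        for root_el in plant.findall("root"):
            _read_axis(root_el, 1, None, factor, axes, counter)
        systems.append(
            RootSystem(
                plant_id=plant.get("id", "plant"),
                accession=plant.get("label", "unknown"),
                axes=axes,
                scale=factor,
            )
        )
    return systems
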