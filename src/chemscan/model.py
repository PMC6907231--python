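"""In-memory model of one chemical drawing, plus 2-D geometry helpers.

A drawing is held as a :class:`SchemeGraph`: chemical fragments (atoms and
bonds with their drawing coordinates), free text blocks and reaction arrows.
The model is deliberately lossy — fonts, colors and page furniture are gone —
but faithful for extraction: everything role assignment and molecule
reconstruction need survives.

Coordinate convention: drawing units are CDXML "points" and *y grows
downward* (the screen convention of the source formats). "Above the arrow"
therefore means *smaller* y, and the signed perpendicular distance returned
by :func:`project_on_arrow` is negative above a left-to-right arrow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from .errors import GeometryError

__all__ = [
    "Point2D",
    "Rect",
    "NodeKind",
    "AtomNode",
    "BondEdge",
    "BondDisplay",
    "FragmentShape",
    "TextBlock",
    "ArrowStyle",
    "ArrowShape",
    "SchemeGraph",
    "bounding_box",
    "project_on_arrow",
]


@dataclass(frozen=True)
class Point2D:
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise GeometryError(f"non-finite coordinate ({self.x}, {self.y})")

    def translated(self, dx: float, dy: float) -> "Point2D":
        return Point2D(self.x + dx, self.y + dy)


@dataclass(frozen=True)
class Rect:
    min: Point2D
    max: Point2D

    def __post_init__(self) -> None:
        if self.min.x > self.max.x or self.min.y > self.max.y:
            raise GeometryError("Rect min must not exceed max")

    @property
    def center(self) -> Point2D:
        return Point2D((self.min.x + self.max.x) / 2.0, (self.min.y + self.max.y) / 2.0)

    @property
    def width(self) -> float:
        return self.max.x - self.min.x

    @property
    def height(self) -> float:
        return self.max.y - self.min.y

    def contains(self, p: Point2D) -> bool:
        return self.min.x <= p.x <= self.max.x and self.min.y <= p.y <= self.max.y


class NodeKind(str, Enum):
    ELEMENT = "element"
    ABBREVIATION = "abbreviation"
    R_GROUP = "r_group"
    UNKNOWN = "unknown"


class BondDisplay(str, Enum):
    PLAIN = "plain"
    WEDGE = "wedge"
    HASH = "hash"
    DATIVE = "dative"


class ArrowStyle(str, Enum):
    PLAIN = "plain"
    DASHED = "dashed"
    CROSSED = "crossed"


@dataclass
class AtomNode:
    """One drawn node: an element atom, an abbreviation (superatom), or an
    R-group placeholder.

    ``element`` is the atomic number; 0 when the node is not an element
    (abbreviations, R-groups)."""

    id: int
    element: int
    position: Point2D
    charge: int = 0
    isotope: int | None = None
    label: str | None = None
    node_kind: NodeKind = NodeKind.ELEMENT

    def __post_init__(self) -> None:
        if self.node_kind == NodeKind.ELEMENT and self.element < 1:
            raise ValueError(f"element node {self.id} needs atomic number >= 1")
        if self.node_kind == NodeKind.ABBREVIATION and not self.label:
            raise ValueError(f"abbreviation node {self.id} needs a label")


@dataclass
class BondEdge:
    begin: int
    end: int
    order: int | str = 1  # 1, 2, 3 or "aromatic"
    display: BondDisplay = BondDisplay.PLAIN

    def __post_init__(self) -> None:
        if self.begin == self.end:
            raise ValueError("bond endpoints must differ")

    @property
    def coordinative(self) -> bool:
        return self.display == BondDisplay.DATIVE


@dataclass
class FragmentShape:
    id: int
    atoms: list[AtomNode] = field(default_factory=list)
    bonds: list[BondEdge] = field(default_factory=list)

    @property
    def bbox(self) -> Rect:
        return bounding_box(self.atoms)

    def atom_by_id(self, atom_id: int) -> AtomNode:
        for a in self.atoms:
            if a.id == atom_id:
                return a
        raise KeyError(atom_id)

    def validate(self) -> None:
        ids = [a.id for a in self.atoms]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate atom ids in fragment {self.id}")
        idset = set(ids)
        for b in self.bonds:
            if b.begin not in idset or b.end not in idset:
                raise ValueError(
                    f"bond {b.begin}-{b.end} references atoms outside fragment {self.id}"
                )


@dataclass
class TextBlock:
    id: int
    value: str
    bbox: Rect

    def __post_init__(self) -> None:
        self.value = " ".join(self.value.split())
        if not self.value:
            raise ValueError(f"text block {self.id} is empty")


@dataclass
class ArrowShape:
    id: int
    tail: Point2D
    head: Point2D
    style: ArrowStyle = ArrowStyle.PLAIN

    def __post_init__(self) -> None:
        if self.tail == self.head:
            raise GeometryError(f"arrow {self.id} has zero length")

    @property
    def length(self) -> float:
        return math.hypot(self.head.x - self.tail.x, self.head.y - self.tail.y)

    @property
    def bbox(self) -> Rect:
        return Rect(
            Point2D(min(self.tail.x, self.head.x), min(self.tail.y, self.head.y)),
            Point2D(max(self.tail.x, self.head.x), max(self.tail.y, self.head.y)),
        )


@dataclass
class SchemeGraph:
    """One parsed drawing. Object ids are unique across the whole graph
    (readers remap ids into a single namespace; the original ids stay in
    ``source`` provenance when payloads are merged from containers)."""

    fragments: list[FragmentShape] = field(default_factory=list)
    texts: list[TextBlock] = field(default_factory=list)
    arrows: list[ArrowShape] = field(default_factory=list)
    source: str = ""

    def validate(self) -> None:
        seen: set[int] = set()
        for obj in (*self.fragments, *self.texts, *self.arrows):
            if obj.id in seen:
                raise ValueError(f"duplicate object id {obj.id}")
            seen.add(obj.id)
        for f in self.fragments:
            f.validate()

    def median_bond_length(self) -> float:
        """Median drawn bond length, the scale anchor of the drawing.
        Falls back to 30.0 points (the editor default) when no bonds exist."""
        lengths = []
        for f in self.fragments:
            pos = {a.id: a.position for a in f.atoms}
            for b in f.bonds:
                p, q = pos[b.begin], pos[b.end]
                lengths.append(math.hypot(p.x - q.x, p.y - q.y))
        if not lengths:
            return 30.0
        lengths.sort()
        n = len(lengths)
        mid = n // 2
        return lengths[mid] if n % 2 else (lengths[mid - 1] + lengths[mid]) / 2.0


def _extent(obj) -> Rect:
    if isinstance(obj, Point2D):
        return Rect(obj, obj)
    if isinstance(obj, Rect):
        return obj
    if isinstance(obj, AtomNode):
        return Rect(obj.position, obj.position)
    bbox = getattr(obj, "bbox", None)
    if bbox is not None:
        return bbox
    raise TypeError(f"object {obj!r} has no spatial extent")


def bounding_box(objects: Sequence | Iterable) -> Rect:
    """Minimal axis-aligned rectangle enclosing every member's extent.

    Accepts points, rectangles, atoms, or anything with a ``bbox``.
    Raises :class:`GeometryError` for an empty list.
    """
    rects = [_extent(o) for o in objects]
    if not rects:
        raise GeometryError("no objects")
    return Rect(
        Point2D(min(r.min.x for r in rects), min(r.min.y for r in rects)),
        Point2D(max(r.max.x for r in rects), max(r.max.y for r in rects)),
    )


def project_on_arrow(p: Point2D, a: ArrowShape) -> tuple[float, float]:
    """Project ``p`` onto the arrow axis.

    Returns ``(t, d)``: ``t`` is the normalized position along tail→head
    (0 at the tail, 1 at the head) and ``d`` the signed perpendicular
    distance in drawing units.  Sign convention: for a left-to-right arrow,
    points *above* (smaller y) have negative ``d``.

    Both values are invariant under simultaneous translation of the point
    and the arrow; ``t`` is invariant and ``d`` scales under uniform scaling.
    """
    ux, uy = a.head.x - a.tail.x, a.head.y - a.tail.y
    length = math.hypot(ux, uy)
    if length == 0.0:  # unreachable through ArrowShape, kept for raw use
        raise GeometryError("zero-length arrow")
    ux, uy = ux / length, uy / length
    vx, vy = p.x - a.tail.x, p.y - a.tail.y
    t = (vx * ux + vy * uy) / length
    d = ux * vy - uy * vx
    return t, d


def distance_to_segment(p: Point2D, a: ArrowShape) -> float:
    """Euclidean distance from ``p`` to the arrow segment (used for
    nearest-arrow tie-breaking)."""
    t, d = project_on_arrow(p, a)
    if t < 0.0:
        return math.hypot(p.x - a.tail.x, p.y - a.tail.y)
    if t > 1.0:
        return math.hypot(p.x - a.head.x, p.y - a.head.y)
    return abs(d)
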