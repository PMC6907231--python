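"""CDXML (the XML serialization of the ChemDraw object model) → SchemeGraph.

Parsing is deliberately tolerant: every recognized ``n``/``b``/``t``/arrow
element is converted, everything else is skipped with a log entry and never
fatal.  Object ids are remapped to a fresh global namespace so graphs from
several payloads can coexist; the original ids are kept only for error
messages.

Abbreviation nodes that carry their *own* inner fragment (the editor's
expanded form) take the inner fragment as authoritative: the node is
replaced by the expansion and no library lookup will be needed downstream.
"""

from __future__ import annotations

import logging
import re

from lxml import etree

from .errors import NotCdxml
from .model import (
    ArrowShape,
    ArrowStyle,
    AtomNode,
    BondDisplay,
    BondEdge,
    FragmentShape,
    NodeKind,
    Point2D,
    Rect,
    SchemeGraph,
    TextBlock,
)

log = logging.getLogger(__name__)

R_GROUP_PATTERN = re.compile(r"^(R\d*'?|X)$")

# node labels that are plain element symbols stay element nodes
_ELEMENT_BY_SYMBOL: dict[str, int] = {}


def _element_number(symbol: str) -> int | None:
    if not _ELEMENT_BY_SYMBOL:
        from rdkit import Chem

        pt = Chem.GetPeriodicTable()
        for z in range(1, 119):
            _ELEMENT_BY_SYMBOL[pt.GetElementSymbol(z)] = z
    return _ELEMENT_BY_SYMBOL.get(symbol)


# Labels accepted as bare element symbols when no Element attribute confirms
# them.  Deliberately restricted: common superatom labels such as "Ac", "Pr"
# or "Ts" collide with exotic element symbols and must stay abbreviations.
SAFE_ELEMENT_LABELS = {
    "H", "D", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Br", "I",
    "Se", "Sn", "Li", "Na", "K", "Mg", "Al", "Zn", "Pd", "Pt", "Cu", "Fe",
    "Ni", "Ru", "Rh", "Ir", "Ag", "Au", "Hg", "Ti", "Zr", "Mo", "W",
}

_ABBREV_NODE_TYPES = {
    "Nickname",
    "Abbreviation",
    "Unspecified",
    "GenericNickname",
    "Fragment",
}


def classify_label(label: str, element_attr: int | None,
                   node_type: str) -> tuple[NodeKind, int]:
    """Shared label-classification rule for both dialects.

    Returns (kind, element).  An explicit abbreviation node type always wins
    over an element-symbol reading of the label."""
    if R_GROUP_PATTERN.match(label) or node_type == "GenericNickname":
        return NodeKind.R_GROUP, 0
    z = _element_number(label)
    if z is not None:
        if element_attr == z:
            return NodeKind.ELEMENT, z
        if element_attr is None and node_type not in _ABBREV_NODE_TYPES \
                and label in SAFE_ELEMENT_LABELS:
            return NodeKind.ELEMENT, z
        if element_attr is None and node_type == "" and label in SAFE_ELEMENT_LABELS:
            return NodeKind.ELEMENT, z
    if node_type not in _ABBREV_NODE_TYPES and element_attr is not None:
        return NodeKind.ELEMENT, element_attr
    return NodeKind.ABBREVIATION, 0


class _Ids:
    """Fresh global id namespace; remembers the mapping from original ids."""

    def __init__(self) -> None:
        self._next = 1
        self.by_original: dict[str, int] = {}

    def fresh(self, original: str | None = None) -> int:
        new = self._next
        self._next += 1
        if original is not None:
            self.by_original[original] = new
        return new


def parse_coordinate(attr: str) -> Point2D:
    """Parse an ``"x y"`` decimal pair (drawing points)."""
    tokens = attr.split()
    if len(tokens) != 2:
        raise NotCdxml(f"coordinate attribute {attr!r} must have 2 tokens")
    try:
        return Point2D(float(tokens[0]), float(tokens[1]))
    except ValueError as exc:
        raise NotCdxml(f"unparsable coordinate {attr!r}") from exc


def _parse_point3(attr: str) -> Point2D:
    tokens = attr.split()
    if len(tokens) not in (2, 3):
        raise NotCdxml(f"point attribute {attr!r} must have 2 or 3 tokens")
    return Point2D(float(tokens[0]), float(tokens[1]))


def _parse_rect(attr: str) -> Rect:
    tokens = [float(t) for t in attr.split()]
    if len(tokens) != 4:
        raise NotCdxml(f"BoundingBox {attr!r} must have 4 tokens")
    x1, y1, x2, y2 = tokens
    return Rect(Point2D(min(x1, x2), min(y1, y2)), Point2D(max(x1, x2), max(y1, y2)))


def _text_of(el: etree._Element) -> str:
    """Concatenate styled runs (``s`` children) to one plain string."""
    parts = [s.text or "" for s in el.findall("s")]
    if not parts and el.text:
        parts = [el.text]
    return "".join(parts)


def parse_node_element(el: etree._Element, ids: _Ids) -> AtomNode:
    """One ``n`` element → AtomNode.

    Dialect conventions honored: a node without an ``Element`` attribute is
    carbon; a node carrying a textual label and no inner fragment is an
    abbreviation (superatom) unless the label matches the R-group pattern or
    is itself a bare element symbol.
    """
    original = el.get("id")
    p_attr = el.get("p")
    if p_attr is None:
        pos = Point2D(0.0, 0.0)
    else:
        try:
            pos = parse_coordinate(p_attr)
        except NotCdxml as exc:
            raise NotCdxml(f"node {original}: {exc}") from exc
    charge = int(el.get("Charge", "0"))
    isotope = int(el.get("Isotope")) if el.get("Isotope") else None

    label_el = el.find("t")
    label = _text_of(label_el).strip() if label_el is not None else None
    node_type = el.get("NodeType", "")
    element_attr = int(el.get("Element")) if el.get("Element") else None

    if label and el.find("fragment") is None:
        kind, element = classify_label(label, element_attr, node_type)
    else:
        kind = NodeKind.ELEMENT
        element = element_attr if element_attr is not None else 6

    return AtomNode(
        id=ids.fresh(original),
        element=element,
        position=pos,
        charge=charge,
        isotope=isotope,
        label=label or None,
        node_kind=kind,
    )


_ORDER_MAP = {
    "1": 1, "2": 2, "3": 3, "0.5": 1, "1.5": "aromatic", "A": "aromatic",
    "aromatic": "aromatic", "dative": 1,
}

_DISPLAY_MAP = {
    "WedgeBegin": (BondDisplay.WEDGE, False),
    "WedgeEnd": (BondDisplay.WEDGE, True),
    "WedgedHashBegin": (BondDisplay.HASH, False),
    "WedgedHashEnd": (BondDisplay.HASH, True),
    "Dative": (BondDisplay.DATIVE, False),
}


def _parse_bond(el: etree._Element, ids: _Ids) -> BondEdge | None:
    b, e = el.get("B"), el.get("E")
    if b is None or e is None or b not in ids.by_original or e not in ids.by_original:
        log.warning("bond with unresolved endpoints (B=%s E=%s) skipped", b, e)
        return None
    order_attr = el.get("Order", "1")
    order = _ORDER_MAP.get(order_attr)
    if order is None:
        log.warning("unknown bond order %r treated as single", order_attr)
        order = 1
    display, swap = _DISPLAY_MAP.get(el.get("Display", ""), (BondDisplay.PLAIN, False))
    if el.get("Order") == "dative":
        display = BondDisplay.DATIVE
    begin, end = ids.by_original[b], ids.by_original[e]
    if swap:
        begin, end = end, begin
    return BondEdge(begin=begin, end=end, order=order, display=display)


def _parse_fragment(el: etree._Element, ids: _Ids) -> FragmentShape:
    frag = FragmentShape(id=ids.fresh(el.get("id")))
    inline: list[tuple[AtomNode, etree._Element]] = []
    for child in el:
        if child.tag == "n":
            inner = child.find("fragment")
            node = parse_node_element(child, ids)
            if inner is not None:
                # expanded abbreviation: inner fragment is authoritative
                inline.append((node, inner))
            frag.atoms.append(node)
        elif child.tag == "b":
            bond = _parse_bond(child, ids)
            if bond is not None:
                frag.bonds.append(bond)
        else:
            log.debug("skipping %r inside fragment", child.tag)
    for node, inner in inline:
        _inline_inner_fragment(frag, node, inner, ids)
    return frag


def _inline_inner_fragment(
    frag: FragmentShape, node: AtomNode, inner: etree._Element, ids: _Ids
) -> None:
    """Replace an abbreviation node by its own drawn expansion.

    External connection point nodes of the inner fragment mark where the
    outer bonds reattach; without one, the first inner atom is used."""
    inner_frag = _parse_fragment(inner, ids)
    ecp_ids = [
        a.id
        for a, el in zip(
            inner_frag.atoms, [c for c in inner if c.tag == "n"]
        )
        if el.get("NodeType") == "ExternalConnectionPoint"
    ]
    attach_atoms: list[int] = []
    keep_atoms = []
    drop = set()
    for ecp in ecp_ids:
        # the atom bonded to the connection point is the graft site
        for b in inner_frag.bonds:
            if b.begin == ecp:
                attach_atoms.append(b.end)
                break
            if b.end == ecp:
                attach_atoms.append(b.begin)
                break
        drop.add(ecp)
    keep_atoms = [a for a in inner_frag.atoms if a.id not in drop]
    keep_bonds = [b for b in inner_frag.bonds if b.begin not in drop and b.end not in drop]
    if not attach_atoms and keep_atoms:
        attach_atoms = [keep_atoms[0].id]
    # rewire outer bonds that touched the abbreviation node
    k = 0
    for b in frag.bonds:
        target = attach_atoms[min(k, len(attach_atoms) - 1)] if attach_atoms else None
        if b.begin == node.id and target is not None:
            b.begin = target
            k += 1
        elif b.end == node.id and target is not None:
            b.end = target
            k += 1
    frag.atoms = [a for a in frag.atoms if a.id != node.id] + keep_atoms
    frag.bonds.extend(keep_bonds)


def _parse_text(el: etree._Element, ids: _Ids) -> TextBlock | None:
    value = _text_of(el)
    if not value.strip():
        return None
    bbox_attr = el.get("BoundingBox")
    if bbox_attr is not None:
        bbox = _parse_rect(bbox_attr)
    else:
        p = parse_coordinate(el.get("p", "0 0"))
        w = 6.5 * len(value)
        bbox = Rect(Point2D(p.x, p.y - 10.0), Point2D(p.x + w, p.y + 2.0))
    return TextBlock(id=ids.fresh(el.get("id")), value=value, bbox=bbox)


def _arrow_style(el: etree._Element) -> ArrowStyle:
    if el.get("NoGo", "").lower() == "cross":
        return ArrowStyle.CROSSED
    if "Dashed" in el.get("LineType", ""):
        return ArrowStyle.DASHED
    return ArrowStyle.PLAIN


def _parse_arrow(el: etree._Element, ids: _Ids) -> ArrowShape | None:
    head_attr = el.get("Head3D") or el.get("Head")
    tail_attr = el.get("Tail3D") or el.get("Tail")
    if head_attr and tail_attr:
        head, tail = _parse_point3(head_attr), _parse_point3(tail_attr)
    else:
        bbox_attr = el.get("BoundingBox")
        if not bbox_attr:
            return None
        # legacy line graphic: first point is the head, second the tail
        tokens = [float(t) for t in bbox_attr.split()]
        head, tail = Point2D(tokens[0], tokens[1]), Point2D(tokens[2], tokens[3])
    if head == tail:
        log.warning("zero-length arrow skipped")
        return None
    return ArrowShape(id=ids.fresh(el.get("id")), tail=tail, head=head, style=_arrow_style(el))


def _is_arrow_graphic(el: etree._Element) -> bool:
    if el.get("GraphicType") not in ("Line", "Arrow"):
        return False
    return el.get("ArrowType") is not None or el.get("ArrowheadHead") is not None


def parse_cdxml(text: str | bytes, source: str = "") -> SchemeGraph:
    """Parse a CDXML document into a :class:`SchemeGraph`.

    Unknown elements are skipped (logged), never fatal.  Raises
    :class:`NotCdxml` for non-XML input (with the byte offset of the error)
    or for XML whose root is not of the CDXML dialect.
    """
    if isinstance(text, str):
        data = text.encode("utf-8")
    else:
        data = text
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        offset = None
        if exc.position:
            line, col = exc.position
            # recover a byte offset from line/column
            lines = data.split(b"\n")
            offset = sum(len(l) + 1 for l in lines[: line - 1]) + max(col - 1, 0)
        raise NotCdxml(f"input is not XML: {exc.msg}", offset=offset) from exc
    if etree.QName(root).localname != "CDXML":
        raise NotCdxml(f"not CDXML: root element is {root.tag!r}")

    ids = _Ids()
    graph = SchemeGraph(source=source)
    cross_symbols: list[Point2D] = []

    def walk(el: etree._Element) -> None:
        for child in el:
            tag = child.tag if isinstance(child.tag, str) else ""
            if tag in ("page", "group"):
                walk(child)
            elif tag == "fragment":
                graph.fragments.append(_parse_fragment(child, ids))
            elif tag == "t":
                tb = _parse_text(child, ids)
                if tb is not None:
                    graph.texts.append(tb)
            elif tag == "arrow":
                arrow = _parse_arrow(child, ids)
                if arrow is not None:
                    graph.arrows.append(arrow)
            elif tag == "graphic":
                if _is_arrow_graphic(child):
                    arrow = _parse_arrow(child, ids)
                    if arrow is not None:
                        graph.arrows.append(arrow)
                elif child.get("GraphicType") == "Symbol" and child.get("SymbolType") == "NoGo":
                    bbox = child.get("BoundingBox")
                    if bbox:
                        cross_symbols.append(_parse_rect(bbox).center)
                else:
                    log.debug("skipping graphic %r", child.get("GraphicType"))
            else:
                log.debug("skipping unknown element %r", tag)

    walk(root)
    # an X-symbol overlapping an arrow is a strike-through
    for arrow in graph.arrows:
        for c in cross_symbols:
            if arrow.bbox.contains(c):
                arrow.style = ArrowStyle.CROSSED
    graph.validate()
    return graph
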