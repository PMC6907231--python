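"""Writable drawing model and its CDXML / CDX serializers.

A :class:`Drawing` is the writer-side mirror of the reader-side
``SchemeGraph``: fragments of positioned atoms and bonds, centered text
blocks and styled arrows, in the same drawing-point / y-down coordinate
system.  Both the fixture generator and the CDXML exporter build Drawings
and hand them to :func:`to_cdxml` / :func:`to_cdx`, which keeps the two
dialect serializations structurally identical by construction.

Serialization is byte-deterministic: element/attribute order is fixed and
coordinates are rounded to 2 decimals (1/100 point is far below any zone
margin used downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from lxml import etree

from . import cdx_format as F

__all__ = [
    "DrawnAtom", "DrawnBond", "DrawnFragment", "DrawnText", "DrawnArrow",
    "Drawing", "to_cdxml", "to_cdx",
]


@dataclass
class DrawnAtom:
    id: int
    x: float
    y: float
    element: int = 6
    charge: int = 0
    isotope: int | None = None
    label: str | None = None
    kind: str = "element"  # element | abbreviation | r_group


@dataclass
class DrawnBond:
    id: int
    begin: int
    end: int
    order: int | str = 1  # 1,2,3,"aromatic"
    display: str = "plain"  # plain | wedge | hash | dative


@dataclass
class DrawnFragment:
    id: int
    atoms: list[DrawnAtom] = field(default_factory=list)
    bonds: list[DrawnBond] = field(default_factory=list)


@dataclass
class DrawnText:
    """Text block positioned by its center."""

    id: int
    value: str
    cx: float
    cy: float
    width: float = 0.0
    height: float = 12.0

    def __post_init__(self) -> None:
        if self.width <= 0.0:
            self.width = max(6.5 * len(self.value), 4.0)


@dataclass
class DrawnArrow:
    id: int
    tail: tuple[float, float]
    head: tuple[float, float]
    style: str = "plain"  # plain | dashed | crossed


@dataclass
class Drawing:
    fragments: list[DrawnFragment] = field(default_factory=list)
    texts: list[DrawnText] = field(default_factory=list)
    arrows: list[DrawnArrow] = field(default_factory=list)
    bond_length: float = 30.0

    def translate(self, dx: float, dy: float) -> "Drawing":
        out = Drawing(bond_length=self.bond_length)
        for f in self.fragments:
            out.fragments.append(DrawnFragment(
                id=f.id,
                atoms=[DrawnAtom(a.id, a.x + dx, a.y + dy, a.element, a.charge,
                                 a.isotope, a.label, a.kind) for a in f.atoms],
                bonds=[DrawnBond(b.id, b.begin, b.end, b.order, b.display)
                       for b in f.bonds],
            ))
        out.texts = [DrawnText(t.id, t.value, t.cx + dx, t.cy + dy, t.width, t.height)
                     for t in self.texts]
        out.arrows = [DrawnArrow(a.id, (a.tail[0] + dx, a.tail[1] + dy),
                                 (a.head[0] + dx, a.head[1] + dy), a.style)
                      for a in self.arrows]
        return out

    def scale(self, s: float) -> "Drawing":
        out = Drawing(bond_length=self.bond_length * s)
        for f in self.fragments:
            out.fragments.append(DrawnFragment(
                id=f.id,
                atoms=[DrawnAtom(a.id, a.x * s, a.y * s, a.element, a.charge,
                                 a.isotope, a.label, a.kind) for a in f.atoms],
                bonds=[DrawnBond(b.id, b.begin, b.end, b.order, b.display)
                       for b in f.bonds],
            ))
        out.texts = [DrawnText(t.id, t.value, t.cx * s, t.cy * s,
                               t.width * s, t.height * s) for t in self.texts]
        out.arrows = [DrawnArrow(a.id, (a.tail[0] * s, a.tail[1] * s),
                                 (a.head[0] * s, a.head[1] * s), a.style)
                      for a in self.arrows]
        return out


def _num(v: float) -> str:
    s = f"{v:.2f}"
    return s.rstrip("0").rstrip(".") if "." in s else s


_ORDER_TO_CDXML = {1: "1", 2: "2", 3: "3", "aromatic": "1.5"}
_DISPLAY_TO_CDXML = {"wedge": "WedgeBegin", "hash": "WedgedHashBegin",
                     "dative": "Dative"}


def to_cdxml(d: Drawing) -> str:
    root = etree.Element("CDXML", BondLength=_num(d.bond_length))
    page = etree.SubElement(root, "page", id="1")
    for f in d.fragments:
        fel = etree.SubElement(page, "fragment", id=str(f.id))
        for a in f.atoms:
            nel = etree.SubElement(fel, "n", id=str(a.id),
                                   p=f"{_num(a.x)} {_num(a.y)}")
            if a.kind == "element":
                if a.element != 6:
                    nel.set("Element", str(a.element))
            elif a.kind == "abbreviation":
                nel.set("NodeType", "Nickname")
            elif a.kind == "r_group":
                nel.set("NodeType", "GenericNickname")
            if a.charge:
                nel.set("Charge", str(a.charge))
            if a.isotope:
                nel.set("Isotope", str(a.isotope))
            if a.label and a.kind != "element":
                tel = etree.SubElement(nel, "t", p=f"{_num(a.x)} {_num(a.y)}")
                sel = etree.SubElement(tel, "s")
                sel.text = a.label
        for b in f.bonds:
            bel = etree.SubElement(fel, "b", id=str(b.id),
                                   B=str(b.begin), E=str(b.end))
            order = _ORDER_TO_CDXML[b.order]
            if order != "1":
                bel.set("Order", order)
            if b.display in _DISPLAY_TO_CDXML:
                bel.set("Display", _DISPLAY_TO_CDXML[b.display])
    for t in d.texts:
        left, top = t.cx - t.width / 2, t.cy - t.height / 2
        right, bottom = t.cx + t.width / 2, t.cy + t.height / 2
        tel = etree.SubElement(page, "t", id=str(t.id),
                               p=f"{_num(left)} {_num(bottom - 2)}")
        tel.set("BoundingBox", f"{_num(left)} {_num(top)} {_num(right)} {_num(bottom)}")
        sel = etree.SubElement(tel, "s")
        sel.text = t.value
    for a in d.arrows:
        ael = etree.SubElement(page, "arrow", id=str(a.id))
        ael.set("Tail3D", f"{_num(a.tail[0])} {_num(a.tail[1])} 0")
        ael.set("Head3D", f"{_num(a.head[0])} {_num(a.head[1])} 0")
        ael.set("ArrowheadHead", "Full")
        if a.style == "dashed":
            ael.set("LineType", "Dashed")
        elif a.style == "crossed":
            ael.set("NoGo", "Cross")
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True).decode("utf-8")


_ORDER_TO_CDX = {1: F.ORDER_SINGLE, 2: F.ORDER_DOUBLE, 3: F.ORDER_TRIPLE,
                 "aromatic": F.ORDER_AROMATIC}
_DISPLAY_TO_CDX = {"plain": F.DISPLAY_SOLID, "wedge": F.DISPLAY_WEDGE_BEGIN,
                   "hash": F.DISPLAY_HASH_BEGIN, "dative": F.DISPLAY_DATIVE}


def to_cdx(d: Drawing) -> bytes:
    """Serialize to the binary dialect (same object model, TLV encoded)."""
    next_id = 1 + max(
        [a.id for f in d.fragments for a in f.atoms]
        + [b.id for f in d.fragments for b in f.bonds]
        + [t.id for t in d.texts] + [a.id for a in d.arrows] + [1],
    )

    def take_id() -> int:
        nonlocal next_id
        next_id += 1
        return next_id - 1

    page_children = b""
    for f in d.fragments:
        frag_children = b""
        for a in f.atoms:
            props = F.property_record(F.PROP_2D_POSITION, F.pack_point2d(a.x, a.y))
            if a.kind == "element":
                if a.element != 6:
                    props += F.property_record(F.PROP_NODE_ELEMENT,
                                               F.pack_u16(a.element))
            elif a.kind == "abbreviation":
                props += F.property_record(F.PROP_NODE_TYPE,
                                           F.pack_u16(F.NODETYPE_NICKNAME))
            elif a.kind == "r_group":
                props += F.property_record(F.PROP_NODE_TYPE,
                                           F.pack_u16(F.NODETYPE_GENERIC))
            if a.charge:
                props += F.property_record(F.PROP_ATOM_CHARGE,
                                           bytes([a.charge & 0xFF]))
            if a.isotope:
                props += F.property_record(F.PROP_ATOM_ISOTOPE,
                                           F.pack_u16(a.isotope))
            if a.label and a.kind != "element":
                label_obj = F.object_record(
                    F.OBJ_TEXT, take_id(),
                    F.property_record(F.PROP_TEXT, F.pack_text(a.label)))
                props += label_obj
            frag_children += F.object_record(F.OBJ_NODE, a.id, props)
        for b in f.bonds:
            props = (F.property_record(F.PROP_BOND_BEGIN, F.pack_u32(b.begin))
                     + F.property_record(F.PROP_BOND_END, F.pack_u32(b.end)))
            if b.display == "dative":
                props += F.property_record(F.PROP_BOND_ORDER,
                                           F.pack_u16(F.ORDER_DATIVE))
            else:
                props += F.property_record(F.PROP_BOND_ORDER,
                                           F.pack_u16(_ORDER_TO_CDX[b.order]))
            if b.display != "plain":
                props += F.property_record(F.PROP_BOND_DISPLAY,
                                           F.pack_u16(_DISPLAY_TO_CDX[b.display]))
            frag_children += F.object_record(F.OBJ_BOND, b.id, props)
        page_children += F.object_record(F.OBJ_FRAGMENT, f.id, frag_children)

    for t in d.texts:
        left, top = t.cx - t.width / 2, t.cy - t.height / 2
        right, bottom = t.cx + t.width / 2, t.cy + t.height / 2
        bbox = (F.pack_fixed(top) + F.pack_fixed(left)
                + F.pack_fixed(bottom) + F.pack_fixed(right))
        props = (F.property_record(F.PROP_2D_POSITION,
                                   F.pack_point2d(left, bottom - 2))
                 + F.property_record(F.PROP_BOUNDING_BOX, bbox)
                 + F.property_record(F.PROP_TEXT, F.pack_text(t.value)))
        page_children += F.object_record(F.OBJ_TEXT, t.id, props)

    for a in d.arrows:
        props = (F.property_record(F.PROP_GRAPHIC_TYPE, F.pack_u16(F.GRAPHIC_LINE))
                 + F.property_record(F.PROP_ARROW_TYPE,
                                     F.pack_u16(F.ARROWTYPE_FULLHEAD))
                 + F.property_record(F.PROP_HEAD_3D, F.pack_point3d(*a.head))
                 + F.property_record(F.PROP_TAIL_3D, F.pack_point3d(*a.tail)))
        if a.style == "dashed":
            props += F.property_record(F.PROP_LINE_TYPE,
                                       F.pack_u16(F.LINETYPE_DASHED))
        elif a.style == "crossed":
            props += F.property_record(F.PROP_ARROW_NOGO,
                                       F.pack_u16(F.NOGO_CROSS))
        page_children += F.object_record(F.OBJ_GRAPHIC, a.id, props)

    page = F.object_record(F.OBJ_PAGE, take_id(), page_children)
    doc = F.object_record(F.OBJ_DOCUMENT, take_id(), page)
    return F.MAGIC + F.HEADER_RESERVED + doc
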