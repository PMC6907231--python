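"""CDX (the binary ChemDraw dialect) → SchemeGraph.

The reader walks the tag-length-value record tree (see ``cdx_format``),
decodes the property subset extraction needs and skips everything else with
a log entry.  The resulting graph is the same model the CDXML reader
produces, so the two dialects are interchangeable downstream.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field

from . import cdx_format as F
from .cdxml_reader import classify_label
from .errors import NotCdx
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


@dataclass
class CdxRecord:
    """One node of the TLV tree: an object (with children) or a property."""

    tag: int
    obj_id: int = 0
    payload: bytes = b""
    children: list["CdxRecord"] = field(default_factory=list)

    @property
    def is_object(self) -> bool:
        return bool(self.tag & 0x8000)

    def properties(self) -> dict[int, bytes]:
        return {c.tag: c.payload for c in self.children if not c.is_object}

    def objects(self, tag: int | None = None) -> list["CdxRecord"]:
        return [c for c in self.children if c.is_object and (tag is None or c.tag == tag)]


class _Stream:
    def __init__(self, data: bytes, pos: int = 0):
        self.data = data
        self.pos = pos

    def remaining(self) -> int:
        return len(self.data) - self.pos

    def read(self, n: int) -> bytes:
        if self.remaining() < n:
            raise NotCdx("truncated record", offset=self.pos)
        chunk = self.data[self.pos : self.pos + n]
        self.pos += n
        return chunk

    def u16(self) -> int:
        return struct.unpack("<H", self.read(2))[0]

    def u32(self) -> int:
        return struct.unpack("<I", self.read(4))[0]


def read_record_tree(stream: _Stream) -> list[CdxRecord]:
    """Read sibling records until a zero tag or end of stream.

    Every byte is either consumed into a record or attributed to a skipped
    one; unbalanced object nesting raises :class:`NotCdx` with the offset."""
    records: list[CdxRecord] = []
    while stream.remaining() >= 2:
        tag = stream.u16()
        if tag == 0:
            return records
        if tag & 0x8000:
            start = stream.pos
            if stream.remaining() < 4:
                raise NotCdx("truncated object id", offset=start)
            obj_id = stream.u32()
            children = _read_children(stream)
            records.append(CdxRecord(tag=tag, obj_id=obj_id, children=children))
        else:
            length = stream.u16()
            if length == 0xFFFF:
                length = stream.u32()
            if stream.remaining() < length:
                raise NotCdx(f"property 0x{tag:04X} length {length} overruns file",
                             offset=stream.pos)
            records.append(CdxRecord(tag=tag, payload=stream.read(length)))
    if stream.remaining() == 1:
        raise NotCdx("dangling byte at end of stream", offset=stream.pos)
    return records


def _read_children(stream: _Stream) -> list[CdxRecord]:
    children: list[CdxRecord] = []
    while True:
        if stream.remaining() < 2:
            raise NotCdx("unbalanced object nesting", offset=stream.pos)
        tag = struct.unpack_from("<H", stream.data, stream.pos)[0]
        if tag == 0:
            stream.pos += 2
            return children
        sub = _read_subtree(stream)
        children.append(sub)


def _read_subtree(stream: _Stream) -> CdxRecord:
    tag = stream.u16()
    if tag & 0x8000:
        obj_id = stream.u32()
        return CdxRecord(tag=tag, obj_id=obj_id, children=_read_children(stream))
    length = stream.u16()
    if length == 0xFFFF:
        length = stream.u32()
    if stream.remaining() < length:
        raise NotCdx(f"property 0x{tag:04X} length {length} overruns file",
                     offset=stream.pos)
    return CdxRecord(tag=tag, payload=stream.read(length))


def decode_property(tag: int, payload: bytes):
    """Decode one supported property payload to a typed value.

    Raises :class:`NotCdx` when the payload width is inconsistent with the
    tag's declared layout."""
    def need(n: int) -> None:
        if len(payload) != n:
            raise NotCdx(f"property 0x{tag:04X} expects {n} bytes, got {len(payload)}")

    if tag == F.PROP_2D_POSITION:
        need(8)
        y = F.unpack_fixed(payload, 0)
        x = F.unpack_fixed(payload, 4)
        return Point2D(x, y)
    if tag in (F.PROP_HEAD_3D, F.PROP_TAIL_3D):
        need(12)
        return Point2D(F.unpack_fixed(payload, 0), F.unpack_fixed(payload, 4))
    if tag == F.PROP_BOUNDING_BOX:
        need(16)
        # stored top, left, bottom, right
        top, left = F.unpack_fixed(payload, 0), F.unpack_fixed(payload, 4)
        bottom, right = F.unpack_fixed(payload, 8), F.unpack_fixed(payload, 12)
        return Rect(Point2D(min(left, right), min(top, bottom)),
                    Point2D(max(left, right), max(top, bottom)))
    if tag == F.PROP_ATOM_CHARGE:
        if len(payload) == 1:
            return struct.unpack("<b", payload)[0]
        need(4)
        return struct.unpack("<i", payload)[0]
    if tag in (F.PROP_NODE_TYPE, F.PROP_NODE_ELEMENT, F.PROP_ATOM_ISOTOPE,
               F.PROP_BOND_ORDER, F.PROP_BOND_DISPLAY, F.PROP_GRAPHIC_TYPE,
               F.PROP_LINE_TYPE, F.PROP_ARROW_TYPE, F.PROP_ARROW_NOGO):
        need(2)
        return struct.unpack("<H", payload)[0]
    if tag in (F.PROP_BOND_BEGIN, F.PROP_BOND_END):
        need(4)
        return struct.unpack("<I", payload)[0]
    if tag == F.PROP_TEXT:
        return F.unpack_text(payload)
    raise NotCdx(f"property 0x{tag:04X} is not in the supported table")


_ORDER_FROM_BITS = {
    F.ORDER_SINGLE: 1,
    F.ORDER_DOUBLE: 2,
    F.ORDER_TRIPLE: 3,
    F.ORDER_AROMATIC: "aromatic",
}

_DISPLAY_FROM_CODE = {
    F.DISPLAY_SOLID: (BondDisplay.PLAIN, False),
    F.DISPLAY_HASH_BEGIN: (BondDisplay.HASH, False),
    F.DISPLAY_HASH_END: (BondDisplay.HASH, True),
    F.DISPLAY_WEDGE_BEGIN: (BondDisplay.WEDGE, False),
    F.DISPLAY_WEDGE_END: (BondDisplay.WEDGE, True),
    F.DISPLAY_DATIVE: (BondDisplay.DATIVE, False),
}


class _Ids:
    def __init__(self) -> None:
        self._next = 1
        self.by_original: dict[int, int] = {}

    def fresh(self, original: int | None = None) -> int:
        new = self._next
        self._next += 1
        if original is not None:
            self.by_original[original] = new
        return new


def _node_from_record(rec: CdxRecord, ids: _Ids) -> AtomNode:
    props = rec.properties()
    pos = Point2D(0.0, 0.0)
    if F.PROP_2D_POSITION in props:
        pos = decode_property(F.PROP_2D_POSITION, props[F.PROP_2D_POSITION])
    charge = decode_property(F.PROP_ATOM_CHARGE, props[F.PROP_ATOM_CHARGE]) \
        if F.PROP_ATOM_CHARGE in props else 0
    isotope = decode_property(F.PROP_ATOM_ISOTOPE, props[F.PROP_ATOM_ISOTOPE]) \
        if F.PROP_ATOM_ISOTOPE in props else None
    node_type = decode_property(F.PROP_NODE_TYPE, props[F.PROP_NODE_TYPE]) \
        if F.PROP_NODE_TYPE in props else F.NODETYPE_UNSPECIFIED
    label = None
    for t in rec.objects(F.OBJ_TEXT):
        tprops = t.properties()
        if F.PROP_TEXT in tprops:
            label = decode_property(F.PROP_TEXT, tprops[F.PROP_TEXT]).strip()
            break

    _NODETYPE_NAMES = {F.NODETYPE_NICKNAME: "Nickname",
                       F.NODETYPE_GENERIC: "GenericNickname",
                       F.NODETYPE_EXTERNAL_CONNECTION: "ExternalConnectionPoint"}
    element_prop = decode_property(F.PROP_NODE_ELEMENT, props[F.PROP_NODE_ELEMENT]) \
        if F.PROP_NODE_ELEMENT in props else None
    if label and not rec.objects(F.OBJ_FRAGMENT):
        kind, element = classify_label(label, element_prop,
                                       _NODETYPE_NAMES.get(node_type, ""))
    else:
        kind = NodeKind.ELEMENT
        element = element_prop if element_prop is not None else 6

    return AtomNode(id=ids.fresh(rec.obj_id), element=element, position=pos,
                    charge=charge, isotope=isotope, label=label or None, node_kind=kind)


def _fragment_from_record(rec: CdxRecord, ids: _Ids) -> FragmentShape:
    frag = FragmentShape(id=ids.fresh(rec.obj_id))
    inline: list[tuple[AtomNode, CdxRecord]] = []
    for child in rec.objects(F.OBJ_NODE):
        node = _node_from_record(child, ids)
        inner = child.objects(F.OBJ_FRAGMENT)
        if inner:
            inline.append((node, inner[0]))
        frag.atoms.append(node)
    for child in rec.objects(F.OBJ_BOND):
        props = child.properties()
        if F.PROP_BOND_BEGIN not in props or F.PROP_BOND_END not in props:
            log.warning("bond %d without endpoints skipped", child.obj_id)
            continue
        b = decode_property(F.PROP_BOND_BEGIN, props[F.PROP_BOND_BEGIN])
        e = decode_property(F.PROP_BOND_END, props[F.PROP_BOND_END])
        if b not in ids.by_original or e not in ids.by_original:
            log.warning("bond %d references unknown atoms", child.obj_id)
            continue
        order_bits = decode_property(F.PROP_BOND_ORDER, props[F.PROP_BOND_ORDER]) \
            if F.PROP_BOND_ORDER in props else F.ORDER_SINGLE
        display_code = decode_property(F.PROP_BOND_DISPLAY, props[F.PROP_BOND_DISPLAY]) \
            if F.PROP_BOND_DISPLAY in props else F.DISPLAY_SOLID
        display, swap = _DISPLAY_FROM_CODE.get(display_code, (BondDisplay.PLAIN, False))
        if order_bits & F.ORDER_DATIVE:
            display = BondDisplay.DATIVE
            order = 1
        else:
            order = _ORDER_FROM_BITS.get(order_bits, 1)
        begin, end = ids.by_original[b], ids.by_original[e]
        if swap:
            begin, end = end, begin
        frag.bonds.append(BondEdge(begin=begin, end=end, order=order, display=display))
    for node, inner_rec in inline:
        _inline_inner(frag, node, inner_rec, ids)
    return frag


def _inline_inner(frag: FragmentShape, node: AtomNode, inner_rec: CdxRecord,
                  ids: _Ids) -> None:
    inner = _fragment_from_record(inner_rec, ids)
    ecp = [a.id for a, rec in zip(inner.atoms, inner_rec.objects(F.OBJ_NODE))
           if rec.properties().get(F.PROP_NODE_TYPE) is not None and
           decode_property(F.PROP_NODE_TYPE, rec.properties()[F.PROP_NODE_TYPE])
           == F.NODETYPE_EXTERNAL_CONNECTION]
    attach: list[int] = []
    drop = set(ecp)
    for e in ecp:
        for b in inner.bonds:
            if b.begin == e:
                attach.append(b.end)
                break
            if b.end == e:
                attach.append(b.begin)
                break
    keep_atoms = [a for a in inner.atoms if a.id not in drop]
    keep_bonds = [b for b in inner.bonds if b.begin not in drop and b.end not in drop]
    if not attach and keep_atoms:
        attach = [keep_atoms[0].id]
    k = 0
    for b in frag.bonds:
        if attach and b.begin == node.id:
            b.begin = attach[min(k, len(attach) - 1)]
            k += 1
        elif attach and b.end == node.id:
            b.end = attach[min(k, len(attach) - 1)]
            k += 1
    frag.atoms = [a for a in frag.atoms if a.id != node.id] + keep_atoms
    frag.bonds.extend(keep_bonds)


def _text_from_record(rec: CdxRecord, ids: _Ids) -> TextBlock | None:
    props = rec.properties()
    if F.PROP_TEXT not in props:
        return None
    value = decode_property(F.PROP_TEXT, props[F.PROP_TEXT])
    if not value.strip():
        return None
    if F.PROP_BOUNDING_BOX in props:
        bbox = decode_property(F.PROP_BOUNDING_BOX, props[F.PROP_BOUNDING_BOX])
    else:
        p = decode_property(F.PROP_2D_POSITION, props.get(F.PROP_2D_POSITION, b"\0" * 8))
        w = 6.5 * len(value)
        bbox = Rect(Point2D(p.x, p.y - 10.0), Point2D(p.x + w, p.y + 2.0))
    return TextBlock(id=ids.fresh(rec.obj_id), value=value, bbox=bbox)


def _graphic_to_arrow(rec: CdxRecord, ids: _Ids) -> ArrowShape | None:
    props = rec.properties()
    gtype = decode_property(F.PROP_GRAPHIC_TYPE, props[F.PROP_GRAPHIC_TYPE]) \
        if F.PROP_GRAPHIC_TYPE in props else None
    if gtype != F.GRAPHIC_LINE or F.PROP_ARROW_TYPE not in props:
        return None
    if F.PROP_HEAD_3D in props and F.PROP_TAIL_3D in props:
        head = decode_property(F.PROP_HEAD_3D, props[F.PROP_HEAD_3D])
        tail = decode_property(F.PROP_TAIL_3D, props[F.PROP_TAIL_3D])
    elif F.PROP_BOUNDING_BOX in props:
        payload = props[F.PROP_BOUNDING_BOX]
        # first stored point is the head, second the tail
        head = Point2D(F.unpack_fixed(payload, 4), F.unpack_fixed(payload, 0))
        tail = Point2D(F.unpack_fixed(payload, 12), F.unpack_fixed(payload, 8))
    else:
        return None
    if head == tail:
        return None
    style = ArrowStyle.PLAIN
    if F.PROP_ARROW_NOGO in props and \
            decode_property(F.PROP_ARROW_NOGO, props[F.PROP_ARROW_NOGO]) == F.NOGO_CROSS:
        style = ArrowStyle.CROSSED
    elif F.PROP_LINE_TYPE in props and \
            decode_property(F.PROP_LINE_TYPE, props[F.PROP_LINE_TYPE]) & F.LINETYPE_DASHED:
        style = ArrowStyle.DASHED
    return ArrowShape(id=ids.fresh(rec.obj_id), tail=tail, head=head, style=style)


def parse_cdx(data: bytes, source: str = "") -> SchemeGraph:
    """Parse CDX binary bytes into a :class:`SchemeGraph`.

    Raises :class:`NotCdx` when the 8-byte magic is missing or a record is
    truncated (the error names the byte offset)."""
    if not data.startswith(F.MAGIC):
        raise NotCdx("not CDX: missing magic", offset=0)
    pos = len(F.MAGIC)
    if data[pos:pos + 4] == F.HEADER_RESERVED[:4] and len(data) >= pos + 20:
        pos += 20
    stream = _Stream(data, pos)
    records = read_record_tree(stream)

    ids = _Ids()
    graph = SchemeGraph(source=source)

    def walk(recs: list[CdxRecord]) -> None:
        for rec in recs:
            if not rec.is_object:
                continue
            if rec.tag in (F.OBJ_DOCUMENT, F.OBJ_PAGE, F.OBJ_GROUP):
                walk(rec.children)
            elif rec.tag == F.OBJ_FRAGMENT:
                graph.fragments.append(_fragment_from_record(rec, ids))
            elif rec.tag == F.OBJ_TEXT:
                tb = _text_from_record(rec, ids)
                if tb is not None:
                    graph.texts.append(tb)
            elif rec.tag == F.OBJ_GRAPHIC:
                arrow = _graphic_to_arrow(rec, ids)
                if arrow is not None:
                    graph.arrows.append(arrow)
                else:
                    log.debug("skipping graphic object %d", rec.obj_id)
            else:
                log.debug("skipping object 0x%04X", rec.tag)

    walk(records)
    graph.validate()
    return graph


def find_cdx_end(data: bytes, start: int) -> int:
    """End offset of the record tree beginning at ``start`` (which must point
    at the magic).  Used by signature-scan extraction from containers."""
    pos = start + len(F.MAGIC)
    if data[pos:pos + 4] == F.HEADER_RESERVED[:4] and len(data) >= pos + 20:
        pos += 20
    stream = _Stream(data, pos)
    depth = 0
    seen_object = False
    while stream.remaining() >= 2:
        tag = stream.u16()
        if tag == 0:
            if depth > 0:
                depth -= 1
            if depth == 0 and seen_object:
                break
            continue
        if tag & 0x8000:
            stream.u32()
            depth += 1
            seen_object = True
        else:
            length = stream.u16()
            if length == 0xFFFF:
                length = stream.u32()
            stream.read(length)
    return stream.pos
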