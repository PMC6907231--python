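"""Tag tables and primitives shared by the CDX binary reader and writer.

The binary dialect is a little-endian tagged tree: a 16-bit tag with the
high bit set opens an object (followed by a 32-bit id and child records
until a zero tag); otherwise the tag is a property followed by a 16-bit
payload length (0xFFFF escapes to a 32-bit length for oversized payloads).
Coordinates are 32-bit fixed point (divide by 65536 to get drawing points)
and 2-D positions are stored y-before-x — both documented quirks of the
format.  Only the ~20 properties extraction needs are decoded; everything
else is skip-logged.
"""

from __future__ import annotations

import struct

MAGIC = b"VjCD0100"
# 8-byte signature + 4 reserved bytes + 16 zero bytes
HEADER_RESERVED = b"\x04\x03\x02\x01" + b"\x00" * 16
FIXED_POINT = 65536.0

# object tags (high bit set)
OBJ_DOCUMENT = 0x8000
OBJ_PAGE = 0x8001
OBJ_GROUP = 0x8002
OBJ_FRAGMENT = 0x8003
OBJ_NODE = 0x8004
OBJ_BOND = 0x8005
OBJ_TEXT = 0x8006
OBJ_GRAPHIC = 0x8007

# property tags
PROP_2D_POSITION = 0x0200
PROP_BOUNDING_BOX = 0x0204
PROP_HEAD_3D = 0x0205
PROP_TAIL_3D = 0x0206
PROP_NODE_TYPE = 0x0400
PROP_NODE_ELEMENT = 0x0402
PROP_ATOM_ISOTOPE = 0x0420
PROP_ATOM_CHARGE = 0x0421
PROP_BOND_ORDER = 0x0600
PROP_BOND_DISPLAY = 0x0601
PROP_BOND_BEGIN = 0x0604
PROP_BOND_END = 0x0605
PROP_TEXT = 0x0700
PROP_GRAPHIC_TYPE = 0x0A00
PROP_LINE_TYPE = 0x0A01
PROP_ARROW_TYPE = 0x0A02
PROP_ARROW_NOGO = 0x0A0B

# node types
NODETYPE_UNSPECIFIED = 0
NODETYPE_ELEMENT = 1
NODETYPE_NICKNAME = 5
NODETYPE_GENERIC = 7
NODETYPE_EXTERNAL_CONNECTION = 12

# bond order bit values
ORDER_SINGLE = 0x0001
ORDER_DOUBLE = 0x0002
ORDER_TRIPLE = 0x0004
ORDER_AROMATIC = 0x0080
ORDER_DATIVE = 0x0100

# bond display values
DISPLAY_SOLID = 0
DISPLAY_HASH_BEGIN = 3
DISPLAY_HASH_END = 4
DISPLAY_WEDGE_BEGIN = 6
DISPLAY_WEDGE_END = 7
DISPLAY_DATIVE = 12

# graphic types / styles
GRAPHIC_LINE = 1
GRAPHIC_SYMBOL = 6
LINETYPE_SOLID = 0
LINETYPE_DASHED = 1
ARROWTYPE_FULLHEAD = 2
NOGO_CROSS = 2


def pack_u16(v: int) -> bytes:
    return struct.pack("<H", v)


def pack_u32(v: int) -> bytes:
    return struct.pack("<I", v)


def pack_fixed(v: float) -> bytes:
    return struct.pack("<i", round(v * FIXED_POINT))


def unpack_fixed(data: bytes, offset: int = 0) -> float:
    return struct.unpack_from("<i", data, offset)[0] / FIXED_POINT


def pack_point2d(x: float, y: float) -> bytes:
    """2-D positions are serialized y-before-x."""
    return pack_fixed(y) + pack_fixed(x)


def pack_point3d(x: float, y: float, z: float = 0.0) -> bytes:
    """3-D points are serialized x, y, z."""
    return pack_fixed(x) + pack_fixed(y) + pack_fixed(z)


def pack_text(value: str) -> bytes:
    """Text payload: 16-bit style-run count, 10 bytes per run, then bytes
    (Latin-1, the legacy editor default)."""
    run = struct.pack("<HHHHH", 0, 0, 0, 10, 0)  # one run from offset 0
    return pack_u16(1) + run + value.encode("latin-1", errors="replace")


def unpack_text(payload: bytes) -> str:
    if len(payload) < 2:
        return ""
    nruns = struct.unpack_from("<H", payload, 0)[0]
    start = 2 + 10 * nruns
    if start > len(payload):  # malformed run table: take everything
        start = 2
    return payload[start:].decode("latin-1", errors="replace")


def property_record(tag: int, payload: bytes) -> bytes:
    if len(payload) >= 0xFFFF:
        return pack_u16(tag) + pack_u16(0xFFFF) + pack_u32(len(payload)) + payload
    return pack_u16(tag) + pack_u16(len(payload)) + payload


def object_record(tag: int, obj_id: int, children: bytes) -> bytes:
    return pack_u16(tag) + pack_u32(obj_id) + children + pack_u16(0)
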