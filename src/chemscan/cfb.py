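"""Minimal OLE compound-file (CFB) reader and writer.

This is the structured-storage container behind DOC files and embedded
OLE objects in DOCX archives.  The reader supports version-3 files (512-byte
sectors) with FAT and mini-FAT chains and exposes streams by path; the
writer produces small standards-conforming containers (header, DIFAT in
header, FAT, directory red-black tree flattened to sibling chains, mini
stream for streams under the 4096-byte cutoff).  Round-tripping a stream
through write+read is byte-identity, which is what container extraction
tests rely on.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

from .errors import NotDoc

MAGIC = b"\xd0\xcf\x11\xe0\xa1\xb1\x1a\xe1"
ENDOFCHAIN = 0xFFFFFFFE
FREESECT = 0xFFFFFFFF
FATSECT = 0xFFFFFFFD
NOSTREAM = 0xFFFFFFFF

SECTOR = 512
MINISECTOR = 64
MINI_CUTOFF = 4096

TYPE_STORAGE = 1
TYPE_STREAM = 2
TYPE_ROOT = 5


@dataclass
class Entry:
    name: str
    type: int
    start: int
    size: int
    left: int
    right: int
    child: int
    index: int


@dataclass
class CompoundFile:
    entries: list[Entry]
    fat: list[int]
    minifat: list[int]
    sectors: bytes
    mini_stream: bytes

    def _chain(self, start: int) -> list[int]:
        chain, seen = [], set()
        s = start
        while s not in (ENDOFCHAIN, FREESECT) and s < len(self.fat):
            if s in seen:
                raise NotDoc("FAT chain cycle")
            seen.add(s)
            chain.append(s)
            s = self.fat[s]
        return chain

    def _mini_chain(self, start: int) -> list[int]:
        chain, seen = [], set()
        s = start
        while s not in (ENDOFCHAIN, FREESECT) and s < len(self.minifat):
            if s in seen:
                raise NotDoc("mini-FAT chain cycle")
            seen.add(s)
            chain.append(s)
            s = self.minifat[s]
        return chain

    def read_stream(self, entry: Entry) -> bytes:
        if entry.type == TYPE_ROOT or entry.size >= MINI_CUTOFF:
            data = b"".join(self.sectors[s * SECTOR:(s + 1) * SECTOR]
                            for s in self._chain(entry.start))
        else:
            data = b"".join(
                self.mini_stream[s * MINISECTOR:(s + 1) * MINISECTOR]
                for s in self._mini_chain(entry.start))
        return data[:entry.size]

    def walk(self) -> list[tuple[str, Entry]]:
        """All entries as (path, entry), document order (directory order
        within each storage)."""
        out: list[tuple[str, Entry]] = []

        def visit(idx: int, prefix: str, seen: set[int]) -> None:
            if idx == NOSTREAM or idx >= len(self.entries) or idx in seen:
                return
            seen.add(idx)
            e = self.entries[idx]
            visit(e.left, prefix, seen)
            path = prefix + e.name
            out.append((path, e))
            if e.child != NOSTREAM:
                visit(e.child, path + "/", seen)
            visit(e.right, prefix, seen)

        root = self.entries[0]
        if root.child != NOSTREAM:
            visit(root.child, "", set())
        return out

    def streams(self) -> list[tuple[str, bytes]]:
        return [(path, self.read_stream(e)) for path, e in self.walk()
                if e.type == TYPE_STREAM]


def parse(data: bytes) -> CompoundFile:
    if not data.startswith(MAGIC):
        raise NotDoc("not an OLE compound file: bad magic", offset=0)
    if len(data) < SECTOR:
        raise NotDoc("truncated OLE header")
    (num_fat, first_dir, _txn, _cutoff, first_minifat, num_minifat,
     first_difat, num_difat) = struct.unpack_from("<8I", data, 44)
    difat = list(struct.unpack_from("<109I", data, 76))
    # DIFAT continuation sectors
    s = first_difat
    for _ in range(num_difat):
        if s in (ENDOFCHAIN, FREESECT):
            break
        off = SECTOR + s * SECTOR
        block = struct.unpack_from("<128I", data, off)
        difat.extend(block[:127])
        s = block[127]
    fat: list[int] = []
    sectors = data[SECTOR:]
    for fs in difat:
        if fs in (FREESECT, ENDOFCHAIN):
            continue
        off = fs * SECTOR
        if off + SECTOR > len(sectors):
            raise NotDoc("FAT sector out of range", offset=SECTOR + off)
        fat.extend(struct.unpack_from("<128I", sectors, off))

    def chain(start: int) -> list[int]:
        out, seen = [], set()
        cur = start
        while cur not in (ENDOFCHAIN, FREESECT) and cur < len(fat):
            if cur in seen:
                raise NotDoc("directory chain cycle")
            seen.add(cur)
            out.append(cur)
            cur = fat[cur]
        return out

    entries: list[Entry] = []
    for ds in chain(first_dir):
        off = ds * SECTOR
        for k in range(SECTOR // 128):
            raw = sectors[off + k * 128: off + (k + 1) * 128]
            if len(raw) < 128:
                break
            (name_raw, name_len, etype, _color, left, right, child, _clsid,
             _state, _ct, _mt, start, size) = struct.unpack(
                "<64sHBBIII16sIQQIQ", raw)
            if etype == 0:
                name = ""
            else:
                name = name_raw[:max(name_len - 2, 0)].decode(
                    "utf-16-le", errors="replace")
            entries.append(Entry(name=name, type=etype, start=start,
                                 size=size, left=left, right=right,
                                 child=child, index=len(entries)))
    if not entries or entries[0].type != TYPE_ROOT:
        raise NotDoc("missing root directory entry")

    minifat: list[int] = []
    for ms in chain(first_minifat):
        minifat.extend(struct.unpack_from("<128I", sectors, ms * SECTOR))
    cf = CompoundFile(entries=entries, fat=fat, minifat=minifat,
                      sectors=sectors, mini_stream=b"")
    cf.mini_stream = cf.read_stream(entries[0]) if entries[0].size else b""
    return cf


# ------------------------------------------------------------------ writer


@dataclass
class _Node:
    name: str
    data: bytes | None  # None = storage
    children: list["_Node"] = field(default_factory=list)


def _tree_from_mapping(tree: dict) -> list[_Node]:
    nodes = []
    for name, value in tree.items():
        if isinstance(value, dict):
            nodes.append(_Node(name, None, _tree_from_mapping(value)))
        else:
            nodes.append(_Node(name, bytes(value)))
    return nodes


def build(tree: dict) -> bytes:
    """Serialize ``{name: bytes | {nested}}`` into a compound file.

    Sibling order inside a storage follows the mapping order (entries are
    chained through the right pointer, which every conforming reader
    traverses)."""
    roots = _tree_from_mapping(tree)

    flat: list[dict] = []

    def add_entry(node: _Node | None, etype: int, name: str) -> int:
        idx = len(flat)
        flat.append({"name": name, "type": etype,
                     "data": node.data if node else None,
                     "left": NOSTREAM, "right": NOSTREAM, "child": NOSTREAM,
                     "start": ENDOFCHAIN, "size": 0})
        return idx

    root_idx = add_entry(None, TYPE_ROOT, "Root Entry")

    def place(nodes: list[_Node], parent: int) -> None:
        prev = None
        for node in nodes:
            etype = TYPE_STORAGE if node.data is None else TYPE_STREAM
            idx = add_entry(node, etype, node.name)
            if prev is None:
                flat[parent]["child"] = idx
            else:
                flat[prev]["right"] = idx
            prev = idx
            if node.data is None:
                place(node.children, idx)

    place(roots, root_idx)

    # mini stream assembly
    minifat: list[int] = []
    mini_parts: list[bytes] = []
    big: list[tuple[int, bytes]] = []
    for e in flat:
        if e["type"] != TYPE_STREAM:
            continue
        data = e["data"] or b""
        e["size"] = len(data)
        if len(data) < MINI_CUTOFF:
            nsec = max((len(data) + MINISECTOR - 1) // MINISECTOR, 0)
            e["start"] = len(minifat) if nsec else ENDOFCHAIN
            for k in range(nsec):
                minifat.append(len(minifat) + 1 if k < nsec - 1 else ENDOFCHAIN)
            mini_parts.append(data + b"\x00" *
                              (nsec * MINISECTOR - len(data)))
        else:
            big.append((flat.index(e), data))
    mini_stream = b"".join(mini_parts)
    flat[root_idx]["size"] = len(mini_stream)

    def pad_sector(b: bytes) -> bytes:
        n = (len(b) + SECTOR - 1) // SECTOR
        return b + b"\x00" * (n * SECTOR - len(b))

    ndir = (len(flat) * 128 + SECTOR - 1) // SECTOR

    minifat_bytes = b""
    if minifat:
        minifat_bytes = pad_sector(
            b"".join(struct.pack("<I", v) for v in minifat).ljust(
                ((len(minifat) * 4 + SECTOR - 1) // SECTOR) * SECTOR,
                b"\xff"))
    nminifat = len(minifat_bytes) // SECTOR
    ministream_bytes = pad_sector(mini_stream)
    nministream = len(ministream_bytes) // SECTOR
    big_padded = [(idx, pad_sector(data)) for idx, data in big]
    nbig = sum(len(d) // SECTOR for _, d in big_padded)

    # iterate FAT size until stable
    nfat = 1
    while True:
        payload = ndir + nminifat + nministream + nbig
        total = nfat + payload
        needed = (total + 127) // 128
        if needed == nfat:
            break
        nfat = needed
    if nfat > 109:
        raise NotDoc("container too large for the minimal writer")

    fat = [FATSECT] * nfat
    cursor = nfat

    def alloc(nsec: int) -> int:
        nonlocal cursor
        start = cursor
        for k in range(nsec):
            fat.append(start + k + 1 if k < nsec - 1 else ENDOFCHAIN)
        cursor += nsec
        return start if nsec else ENDOFCHAIN

    first_dir = alloc(ndir)
    first_minifat = alloc(nminifat) if nminifat else ENDOFCHAIN
    first_ministream = alloc(nministream) if nministream else ENDOFCHAIN
    for idx, data in big_padded:
        flat[idx]["start"] = alloc(len(data) // SECTOR)
    flat[root_idx]["start"] = first_ministream

    # re-serialize directory with final start sectors
    dir_bytes = b""
    for e in flat:
        name16 = e["name"].encode("utf-16-le") + b"\x00\x00" \
            if e["type"] else b""
        start = e["start"] if e["start"] != ENDOFCHAIN else 0
        if e["type"] == TYPE_ROOT and first_ministream == ENDOFCHAIN:
            start = ENDOFCHAIN
        dir_bytes += struct.pack(
            "<64sHBBIII16sIQQIQ",
            name16.ljust(64, b"\x00")[:64], len(name16), e["type"], 1,
            e["left"], e["right"], e["child"], b"\x00" * 16, 0, 0, 0,
            start, e["size"])
    while len(dir_bytes) % SECTOR:
        dir_bytes += struct.pack("<64sHBBIII16sIQQIQ", b"\x00" * 64, 0, 0, 0,
                                 NOSTREAM, NOSTREAM, NOSTREAM, b"\x00" * 16,
                                 0, 0, 0, 0, 0)

    fat += [FREESECT] * (nfat * 128 - len(fat))
    fat_bytes = b"".join(struct.pack("<I", v) for v in fat)

    difat = [i for i in range(nfat)] + [FREESECT] * (109 - nfat)
    header = MAGIC + b"\x00" * 16
    header += struct.pack("<HHHHH6xIIIIIIIII",
                          0x003E, 0x0003, 0xFFFE, 9, 6,
                          0,  # number of directory sectors (v3: 0)
                          nfat, first_dir, 0, MINI_CUTOFF,
                          first_minifat, nminifat,
                          ENDOFCHAIN, 0)
    header += b"".join(struct.pack("<I", v) for v in difat)
    assert len(header) == SECTOR, len(header)

    body = fat_bytes + dir_bytes + minifat_bytes + ministream_bytes \
        + b"".join(d for _, d in big_padded)
    return header + body
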