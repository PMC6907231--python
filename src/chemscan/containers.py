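"""Extraction of CDX/CDXML payloads from DOC, DOCX and ELN-export XML.

DOCX is a zip archive: embedded objects live under the embeddings
directory, but producers differ, so *every* member that is an OLE file is
descended into (belt and braces) and raw ``.cdx``/``.cdxml`` members are
accepted too.  DOC is an OLE compound file whose object-pool storages hold
the embedded ChemDraw streams; when storage walking finds nothing, a
whole-file signature scan for the CDX magic recovers payloads from mildly
corrupt files.  ELN-export XML carries CDXML islands plus a reaction
table; the table→record field mapping is configuration-driven because the
dialect varies by exporter.
"""

from __future__ import annotations

import io
import logging
import zipfile
from dataclasses import dataclass, field

from lxml import etree

from . import cfb
from .cdx_format import MAGIC as CDX_MAGIC
from .cdx_reader import find_cdx_end
from .errors import NotDoc, NotDocx
from .library import Libraries, canonicalize, resolve_name

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EmbeddedPayload:
    data: bytes
    dialect: str  # cdx | cdxml
    origin: str  # container path + member/stream path + byte offset


_ROLE_SYNONYMS = {
    "reactant": "reactant", "startingmaterial": "reactant",
    "starting material": "reactant",
    "reagent": "reagent", "catalyst": "reagent",
    "solvent": "solvent",
    "product": "product",
}


@dataclass(frozen=True)
class ElnReactionRecord:
    role: str  # reactant | reagent | solvent | product
    identifier: str  # SMILES or name
    amounts: str = ""
    conditions: str = ""
    observations: str = ""


@dataclass(frozen=True)
class Discrepancy:
    kind: str  # missing-in-scheme | missing-in-table | unresolved-identifier
    identifier: str
    smiles: str | None = None
    step_index: int | None = None


def scan_for_cdx_signatures(data: bytes) -> list[int]:
    """Offsets of every occurrence of the 8-byte CDX magic, ascending."""
    offsets, start = [], 0
    while True:
        i = data.find(CDX_MAGIC, start)
        if i < 0:
            return offsets
        offsets.append(i)
        start = i + 1


def _payloads_from_ole(data: bytes, origin_prefix: str) -> list[EmbeddedPayload]:
    out: list[EmbeddedPayload] = []
    try:
        cf = cfb.parse(data)
    except NotDoc:
        return out
    for path, stream in cf.streams():
        if stream.startswith(CDX_MAGIC):
            out.append(EmbeddedPayload(stream, "cdx",
                                       f"{origin_prefix}{path}"))
        elif path.rsplit("/", 1)[-1].lower() == "contents" and \
                CDX_MAGIC in stream[:256]:
            off = stream.find(CDX_MAGIC)
            out.append(EmbeddedPayload(stream[off:], "cdx",
                                       f"{origin_prefix}{path}+{off}"))
    return out


def extract_from_docx(data: bytes, name: str = "docx") -> list[EmbeddedPayload]:
    """Open every embedded-object member of the archive; OLE-wrapped members
    are descended into.  A zip without embeddings yields an empty list."""
    try:
        zf = zipfile.ZipFile(io.BytesIO(data))
    except zipfile.BadZipFile as exc:
        raise NotDocx("not DOCX: not a zip archive") from exc
    payloads: list[EmbeddedPayload] = []
    for info in zf.infolist():
        member = zf.read(info.filename)
        origin = f"{name}!{info.filename}"
        if member.startswith(cfb.MAGIC):
            payloads.extend(_payloads_from_ole(member, origin + "/"))
        elif member.startswith(CDX_MAGIC):
            payloads.append(EmbeddedPayload(member, "cdx", origin))
        elif info.filename.lower().endswith((".cdxml",)):
            payloads.append(EmbeddedPayload(member, "cdxml", origin))
    return payloads


def extract_from_doc(data: bytes, name: str = "doc") -> list[EmbeddedPayload]:
    """Walk the object-pool storages of the compound file; fall back to a
    whole-file signature scan when stream walking finds no payload."""
    if not data.startswith(cfb.MAGIC):
        raise NotDoc("not DOC: missing OLE magic", offset=0)
    payloads: list[EmbeddedPayload] = []
    try:
        payloads = _payloads_from_ole(data, f"{name}!")
    except Exception:  # mildly corrupt files: fall through to the scan
        log.warning("OLE walk of %s failed; falling back to signature scan",
                    name)
    if not payloads:
        for off in scan_for_cdx_signatures(data):
            end = find_cdx_end(data, off)
            payloads.append(EmbeddedPayload(
                data[off:end], "cdx", f"{name}!signature-scan+{off}"))
    return payloads


DEFAULT_ELN_MAPPING = {
    "row_path": ".//reactionTable/row",
    "role": "@role",
    "identifier": "identifier",
    "amounts": "amount",
    "conditions": "conditions",
    "observations": "observation",
}


def _mapped(row: etree._Element, spec: str) -> str:
    if spec.startswith("@"):
        return row.get(spec[1:], "")
    el = row.find(spec)
    return (el.text or "").strip() if el is not None else ""


def extract_from_eln_xml(
    text: str | bytes,
    mapping: dict[str, str] | None = None,
    name: str = "eln",
) -> tuple[list[EmbeddedPayload], list[ElnReactionRecord]]:
    """Separate CDXML islands and reaction-table rows from an ELN export.

    XML without any CDXML island returns ``([], records-or-empty)``."""
    mapping = mapping or DEFAULT_ELN_MAPPING
    data = text.encode("utf-8") if isinstance(text, str) else text
    root = etree.fromstring(data)
    payloads: list[EmbeddedPayload] = []
    candidates = [root] if etree.QName(root).localname == "CDXML" else \
        [el for el in root.iter() if isinstance(el.tag, str)
         and etree.QName(el).localname == "CDXML"]
    for k, island in enumerate(candidates):
        payloads.append(EmbeddedPayload(
            etree.tostring(island), "cdxml", f"{name}!cdxml[{k}]"))
    records: list[ElnReactionRecord] = []
    for row in root.findall(mapping["row_path"]):
        raw_role = _mapped(row, mapping["role"]).strip().lower()
        role = _ROLE_SYNONYMS.get(raw_role)
        if role is None:
            log.warning("unknown reaction-table role %r skipped", raw_role)
            continue
        records.append(ElnReactionRecord(
            role=role,
            identifier=_mapped(row, mapping["identifier"]),
            amounts=_mapped(row, mapping["amounts"]),
            conditions=_mapped(row, mapping["conditions"]),
            observations=_mapped(row, mapping["observations"]),
        ))
    return payloads, records


def _resolve_identifier(identifier: str, libs: Libraries) -> str | None:
    smiles = resolve_name(identifier, libs)
    if smiles is not None:
        return smiles
    return canonicalize(identifier)


def reconcile(steps, records: list[ElnReactionRecord],
              libs: Libraries) -> list[Discrepancy]:
    """Cross-check scheme extraction against the ELN reaction table on the
    basis of canonical SMILES sets.

    Reports table compounds missing from the scheme, scheme compounds
    missing from the table, and identifiers that resolve to no structure
    (reported, never fatal)."""
    out: list[Discrepancy] = []
    table_smiles: dict[str, str] = {}
    for rec in records:
        smiles = _resolve_identifier(rec.identifier, libs)
        if smiles is None:
            out.append(Discrepancy("unresolved-identifier", rec.identifier))
            continue
        table_smiles[smiles] = rec.identifier

    def scheme_set(step) -> set[str]:
        return ({m.cano_smiles for m in step.reactants}
                | {m.cano_smiles for m in step.products}
                | {m.cano_smiles for m in step.reagents}
                | set(step.reagents_smiles) | set(step.solvents_smiles))

    if not steps:
        for smiles, ident in sorted(table_smiles.items()):
            out.append(Discrepancy("missing-in-scheme", ident, smiles))
        return out

    union = set()
    for step in steps:
        union |= scheme_set(step)
    targets = [(step.step_index, scheme_set(step)) for step in steps] \
        if len(steps) == 1 else [(None, union)]
    for step_index, sset in targets:
        for smiles, ident in sorted(table_smiles.items()):
            if smiles not in sset:
                out.append(Discrepancy("missing-in-scheme", ident, smiles,
                                       step_index))
        for smiles in sorted(sset - set(table_smiles)):
            out.append(Discrepancy("missing-in-table", smiles, smiles,
                                   step_index))
    return out
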