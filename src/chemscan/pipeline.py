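"""End-to-end extraction: file bytes → reactions and molecules.

``scan_bytes`` sniffs the input type (CDX magic, zip, OLE, XML dialect),
unwraps container formats, parses every payload into a SchemeGraph and runs
molecule building plus reaction assembly.  ELN exports additionally get
their reaction table reconciled against the scheme extraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree

from . import cfb
from .assembler import (
    AssemblerConfig,
    ReactionStep,
    assemble,
    harvest_rgroup_definitions,
)
from .builder import Molecule, build_molecule
from .cdx_format import MAGIC as CDX_MAGIC
from .cdx_reader import parse_cdx
from .cdxml_reader import parse_cdxml
from .containers import (
    Discrepancy,
    ElnReactionRecord,
    extract_from_doc,
    extract_from_docx,
    extract_from_eln_xml,
    reconcile,
)
from .errors import ChemScanError, MoleculeError
from .library import Libraries, load_libraries
from .model import SchemeGraph
from .textinterp import PatternTable, classify_text_block, default_table

log = logging.getLogger(__name__)


@dataclass
class ExtractionResult:
    source: str
    steps: list[ReactionStep] = field(default_factory=list)
    molecules: list[Molecule] = field(default_factory=list)  # isolated
    records: list[ElnReactionRecord] = field(default_factory=list)
    discrepancies: list[Discrepancy] = field(default_factory=list)
    graph: SchemeGraph | None = None


def scan_graph(
    g: SchemeGraph,
    libs: Libraries | None = None,
    config: AssemblerConfig | None = None,
    table: PatternTable | None = None,
) -> ExtractionResult:
    """Extract reactions and molecules from one parsed drawing."""
    libs = libs if libs is not None else load_libraries()
    config = config or AssemblerConfig()
    table = table or default_table()
    mbl = g.median_bond_length()

    rgroup_defs, consumed = harvest_rgroup_definitions(g)

    molecules: dict[int, Molecule] = {}
    for f in g.fragments:
        if not f.atoms:
            continue
        try:
            molecules[f.id] = build_molecule(f, libs, rgroup_defs, mbl)
        except MoleculeError as exc:
            log.warning("fragment %d skipped: %s", f.id, exc)

    # compound labels: short tokens sitting just below a fragment
    for t in g.texts:
        if t.id in consumed:
            continue
        cls = classify_text_block(t, libs, fragments=g.fragments,
                                  median_bond_length=mbl, table=table)
        if cls.kind == "label":
            center = t.bbox.center
            best, best_d = None, None
            for f in g.fragments:
                if f.id not in molecules or not f.atoms:
                    continue
                fb = f.bbox
                if fb.min.x - mbl <= center.x <= fb.max.x + mbl \
                        and 0.0 <= center.y - fb.max.y <= config.label_dist_bonds * mbl:
                    dist = center.y - fb.max.y
                    if best_d is None or dist < best_d:
                        best, best_d = f.id, dist
            if best is not None:
                molecules[best].label = cls.label
                consumed.add(t.id)

    pruned = SchemeGraph(
        fragments=g.fragments,
        texts=[t for t in g.texts if t.id not in consumed],
        arrows=g.arrows,
        source=g.source,
    )
    steps, isolated = assemble(pruned, molecules, libs, config, table)
    for step in steps:
        step.source = g.source
    return ExtractionResult(source=g.source, steps=steps,
                            molecules=isolated, graph=g)


def _looks_like_xml(data: bytes) -> bool:
    head = data.lstrip()[:200]
    return head.startswith(b"<?xml") or head.startswith(b"<")


def scan_bytes(
    data: bytes,
    source: str = "",
    libs: Libraries | None = None,
    config: AssemblerConfig | None = None,
    table: PatternTable | None = None,
) -> list[ExtractionResult]:
    """Sniff and scan one input file; containers yield one result per
    embedded payload."""
    libs = libs if libs is not None else load_libraries()

    if data.startswith(CDX_MAGIC):
        g = parse_cdx(data, source=source)
        return [scan_graph(g, libs, config, table)]
    if data.startswith(b"PK\x03\x04"):
        results = []
        for payload in extract_from_docx(data, name=source or "docx"):
            g = _parse_payload(payload)
            results.append(scan_graph(g, libs, config, table))
        return results
    if data.startswith(cfb.MAGIC):
        results = []
        for payload in extract_from_doc(data, name=source or "doc"):
            g = _parse_payload(payload)
            results.append(scan_graph(g, libs, config, table))
        return results
    if _looks_like_xml(data):
        root = etree.fromstring(data)
        if etree.QName(root).localname == "CDXML":
            g = parse_cdxml(data, source=source)
            return [scan_graph(g, libs, config, table)]
        payloads, records = extract_from_eln_xml(data, name=source or "eln")
        results = []
        for payload in payloads:
            g = _parse_payload(payload)
            result = scan_graph(g, libs, config, table)
            result.records = records
            result.discrepancies = reconcile(result.steps, records, libs)
            results.append(result)
        if not payloads and records:
            result = ExtractionResult(source=source, records=records,
                                      discrepancies=reconcile([], records, libs))
            results.append(result)
        return results
    raise ChemScanError(
        f"unrecognized input format for {source or 'input'!r}")


def _parse_payload(payload) -> SchemeGraph:
    if payload.dialect == "cdx":
        return parse_cdx(payload.data, source=payload.origin)
    return parse_cdxml(payload.data, source=payload.origin)


def scan_file(path: str | Path, **kwargs) -> list[ExtractionResult]:
    p = Path(path)
    return scan_bytes(p.read_bytes(), source=p.name, **kwargs)
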