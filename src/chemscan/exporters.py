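"""Serialization of extraction results.

Formats: reaction SMILES (``reactants>agents>products``), CML (one
``reaction`` element per step with full atom/bond tables), CDXML (layout
regenerated on a fixed grid: reactants left, band above the arrow,
products right), RFC-4180 CSV / simple spreadsheet, and JSON.
"""

from __future__ import annotations

import csv
import io
import json

from lxml import etree

from .assembler import ReactionStep
from .builder import Molecule
from .drawing import Drawing, DrawnArrow, to_cdxml
from .errors import ChemScanError
from .layout import IdAlloc, make_text, mol_to_placed
from .library import Libraries
from .textinterp import Quantity

CML_NS = "http://www.xml-cml.org/schema"

# fixed export grid (points): deterministic golden files
EXPORT_BOND_LENGTH = 30.0
EXPORT_ARROW_LENGTH = 90.0
EXPORT_BAND_OFFSET = 20.0
EXPORT_GAP = 22.0
EXPORT_ROW_HEIGHT = 300.0


def _quantity_str(q: Quantity | str | None) -> str:
    if q is None:
        return ""
    if isinstance(q, str):
        return q
    return f"{q.value:g} {q.unit}"


def reaction_smiles(step: ReactionStep) -> str:
    """``reactants>agents>products`` with dot-joined canonical components;
    agents are the drawn band reagents plus the text-identified reagents and
    solvents, in drawing order."""
    left = [m.cano_smiles for m in step.reactants if m.cano_smiles]
    right = [m.cano_smiles for m in step.products if m.cano_smiles]
    agents = [s for s in step.agents_smiles if s]
    if not left and not right and not agents:
        raise ChemScanError("cannot render an empty step as reaction SMILES")
    return f"{'.'.join(left)}>{'.'.join(agents)}>{'.'.join(right)}"


# ----------------------------------------------------------------- CML


_CML_ORDER = {1: "S", 2: "D", 3: "T", "aromatic": "A"}


def _cml_molecule(parent: etree._Element, m: Molecule, mol_id: str) -> None:
    mol = etree.SubElement(parent, f"{{{CML_NS}}}molecule", id=mol_id)
    aa = etree.SubElement(mol, f"{{{CML_NS}}}atomArray")
    for i, a in enumerate(m.atoms):
        atom = etree.SubElement(aa, f"{{{CML_NS}}}atom", id=f"{mol_id}a{i + 1}")
        atom.set("elementType", "Du" if a.symbol == "*" else a.symbol)
        atom.set("x2", f"{a.x:.4f}")
        atom.set("y2", f"{-a.y:.4f}")
        if a.charge:
            atom.set("formalCharge", str(a.charge))
        if a.isotope:
            atom.set("isotopeNumber", str(a.isotope))
    ba = etree.SubElement(mol, f"{{{CML_NS}}}bondArray")
    for b in m.bonds:
        bond = etree.SubElement(ba, f"{{{CML_NS}}}bond")
        bond.set("atomRefs2", f"{mol_id}a{b.begin + 1} {mol_id}a{b.end + 1}")
        bond.set("order", "S" if b.coordinative else _CML_ORDER[b.order])


def _cml_scalar(plist: etree._Element, dict_ref: str, value,
                data_type: str = "xsd:string") -> None:
    prop = etree.SubElement(plist, f"{{{CML_NS}}}property", dictRef=dict_ref)
    scalar = etree.SubElement(prop, f"{{{CML_NS}}}scalar", dataType=data_type)
    scalar.text = str(value)


def write_cml(steps: list[ReactionStep]) -> str:
    """CML document: reactantList/productList with molecule tables,
    substanceList for agents, scalar properties for conditions and status."""
    root = etree.Element(f"{{{CML_NS}}}cml", nsmap={None: CML_NS})
    rlist = etree.SubElement(root, f"{{{CML_NS}}}reactionList")
    for k, step in enumerate(steps, 1):
        rxn = etree.SubElement(rlist, f"{{{CML_NS}}}reaction", id=f"r{k}")
        reactants = etree.SubElement(rxn, f"{{{CML_NS}}}reactantList")
        for i, m in enumerate(step.reactants, 1):
            r = etree.SubElement(reactants, f"{{{CML_NS}}}reactant")
            _cml_molecule(r, m, f"r{k}m{i}")
        products = etree.SubElement(rxn, f"{{{CML_NS}}}productList")
        for i, m in enumerate(step.products, 1):
            p = etree.SubElement(products, f"{{{CML_NS}}}product")
            _cml_molecule(p, m, f"r{k}p{i}")
        if step.reagents or step.reagents_smiles or step.solvents_smiles:
            slist = etree.SubElement(rxn, f"{{{CML_NS}}}substanceList")
            for i, m in enumerate(step.reagents, 1):
                s = etree.SubElement(slist, f"{{{CML_NS}}}substance",
                                     role="reagent")
                _cml_molecule(s, m, f"r{k}g{i}")
            for smi in step.reagents_smiles:
                etree.SubElement(slist, f"{{{CML_NS}}}substance",
                                 role="reagent", title=smi)
            for smi in step.solvents_smiles:
                etree.SubElement(slist, f"{{{CML_NS}}}substance",
                                 role="solvent", title=smi)
        plist = etree.SubElement(rxn, f"{{{CML_NS}}}propertyList")
        _cml_scalar(plist, "cs:status", step.status)
        if step.time is not None:
            _cml_scalar(plist, "cs:time", _quantity_str(step.time))
        if step.temperature is not None:
            _cml_scalar(plist, "cs:temperature",
                        _quantity_str(step.temperature))
        if step.yield_percent is not None:
            _cml_scalar(plist, "cs:yield", f"{step.yield_percent:g}",
                        "xsd:double")
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True).decode("utf-8")


# --------------------------------------------------------------- CDXML


def _display_name(smiles: str, libs: Libraries | None) -> str:
    """Preferred textual rendering of a band compound: a library name when
    one maps to this structure, else the SMILES itself (re-parsable as a
    formula on re-extraction)."""
    if libs is not None:
        for key, entries in libs.names.items():
            if entries and entries[0].smiles == smiles:
                return key
    return smiles


def _conditions_text(step: ReactionStep) -> str:
    parts = []
    if step.temperature is not None:
        t = step.temperature
        parts.append(t if isinstance(t, str) else f"{t.value:g} {t.unit}")
    if step.time is not None:
        t = step.time
        parts.append(t if isinstance(t, str) else f"{t.value:g} {t.unit}")
    if step.yield_percent is not None:
        parts.append(f"{step.yield_percent:g}%")
    return ", ".join(parts)


_STYLE_FROM_STATUS = {"success": "plain", "failed": "crossed",
                      "planned": "dashed", "unspecified": "plain"}


def write_cdxml(steps: list[ReactionStep] | list[Molecule],
                libs: Libraries | None = None) -> str:
    """Regenerate a CDXML drawing from extracted steps (or bare molecules).

    The layout is a fixed grid — reactants left, band above the arrow,
    products right, one row per step — chosen so re-extraction through the
    normal pipeline reproduces molecules, roles, conditions and status."""
    ids = IdAlloc()
    d = Drawing(bond_length=EXPORT_BOND_LENGTH)
    molecules_only = all(isinstance(s, Molecule) for s in steps) and steps

    if molecules_only:
        x = 30.0
        for m in steps:
            placed = mol_to_placed(m.cano_smiles, ids, x, 150.0,
                                   EXPORT_BOND_LENGTH)
            d.fragments.append(placed.fragment)
            x = placed.max_x + 2 * EXPORT_GAP
        return to_cdxml(d)

    for row, step in enumerate(steps):
        y = 150.0 + row * EXPORT_ROW_HEIGHT
        x = 30.0
        for i, m in enumerate(step.reactants):
            if i:
                d.texts.append(make_text(ids, "+", x + 4, y))
                x += 18.0
            placed = mol_to_placed(m.cano_smiles, ids, x, y,
                                   EXPORT_BOND_LENGTH)
            d.fragments.append(placed.fragment)
            x = placed.max_x + EXPORT_GAP
        tail = (x, y)
        head = (x + EXPORT_ARROW_LENGTH, y)
        mid_x = x + EXPORT_ARROW_LENGTH / 2
        # drawn reagents are *centered* 45 points above the axis so their
        # bbox centers stay inside the default band half-width
        for j, m in enumerate(step.reagents):
            placed = mol_to_placed(m.cano_smiles, ids, mid_x,
                                   y - 45.0, EXPORT_BOND_LENGTH)
            shift = (mid_x + 34.0 * j) - (placed.min_x + placed.max_x) / 2
            for a in placed.fragment.atoms:
                a.x += shift
            d.fragments.append(placed.fragment)
        band_tokens = [_display_name(s, libs)
                       for s in step.reagents_smiles + step.solvents_smiles]
        cond = _conditions_text(step)
        if cond:
            band_tokens.append(cond)
        if band_tokens:
            d.texts.append(make_text(ids, ", ".join(band_tokens),
                                     mid_x, y + EXPORT_BAND_OFFSET + 8.0))
        d.arrows.append(DrawnArrow(id=ids(), tail=tail, head=head,
                                   style=_STYLE_FROM_STATUS[step.status]))
        x = head[0] + EXPORT_GAP
        for i, m in enumerate(step.products):
            if i:
                d.texts.append(make_text(ids, "+", x + 4, y))
                x += 18.0
            placed = mol_to_placed(m.cano_smiles, ids, x, y,
                                   EXPORT_BOND_LENGTH)
            d.fragments.append(placed.fragment)
            if m.label:
                d.texts.append(make_text(
                    ids, m.label, (placed.min_x + placed.max_x) / 2,
                    placed.max_y + 16.0))
            x = placed.max_x + EXPORT_GAP
    return to_cdxml(d)


# ------------------------------------------------------------- tabular


EXPORT_COLUMNS = ["reaction_smiles", "reactants", "reagents", "products",
                  "solvents", "time", "temperature", "yield", "status",
                  "description", "source"]


def _export_row(step: ReactionStep) -> list[str]:
    return [
        reaction_smiles(step) if (step.reactants or step.products
                                  or step.agents_smiles) else "",
        ";".join(m.cano_smiles for m in step.reactants),
        ";".join([m.cano_smiles for m in step.reagents]
                 + step.reagents_smiles),
        ";".join(m.cano_smiles for m in step.products),
        ";".join(step.solvents_smiles),
        _quantity_str(step.time),
        _quantity_str(step.temperature),
        "" if step.yield_percent is None else f"{step.yield_percent:g}",
        step.status,
        step.description,
        step.source,
    ]


def write_table(steps: list[ReactionStep], format: str = "csv") -> bytes:
    """Header row plus one row per step.  ``csv`` is RFC-4180 quoted;
    ``spreadsheet`` writes the same grid as an xlsx workbook."""
    rows = [EXPORT_COLUMNS] + [_export_row(s) for s in steps]
    if format == "csv":
        buf = io.StringIO()
        writer = csv.writer(buf, quoting=csv.QUOTE_MINIMAL, lineterminator="\r\n")
        writer.writerows(rows)
        return buf.getvalue().encode("utf-8")
    if format == "spreadsheet":
        from openpyxl import Workbook

        wb = Workbook()
        ws = wb.active
        ws.title = "reactions"
        for row in rows:
            ws.append(row)
        out = io.BytesIO()
        wb.save(out)
        return out.getvalue()
    raise ChemScanError(f"unknown table format {format!r}")


# ---------------------------------------------------------------- JSON


def _quantity_json(q: Quantity | str | None):
    if q is None:
        return None
    if isinstance(q, str):
        return {"token": q}
    return {"value": q.value, "unit": q.unit}


def step_to_dict(step: ReactionStep) -> dict:
    return {
        "step_index": step.step_index,
        "status": step.status,
        "incomplete": step.incomplete,
        "reactants": [m.cano_smiles for m in step.reactants],
        "reagents": [m.cano_smiles for m in step.reagents],
        "products": [m.cano_smiles for m in step.products],
        "reagents_smiles": step.reagents_smiles,
        "solvents_smiles": step.solvents_smiles,
        "time": _quantity_json(step.time),
        "temperature": _quantity_json(step.temperature),
        "yield_percent": step.yield_percent,
        "description": step.description,
        "source": step.source,
        "labels": {m.cano_smiles: m.label
                   for m in step.reactants + step.products if m.label},
    }


def write_json(steps: list[ReactionStep],
               molecules: list[Molecule] | None = None) -> str:
    doc = {"reactions": [step_to_dict(s) for s in steps]}
    if molecules is not None:
        doc["molecules"] = [
            {"cano_smiles": m.cano_smiles, "label": m.label} for m in molecules
        ]
    return json.dumps(doc, indent=2, ensure_ascii=False)
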