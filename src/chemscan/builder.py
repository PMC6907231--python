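"""FragmentShape → chemically valid Molecule.

The builder expands superatom abbreviations through the library, applies
the documented edge-case rules (R-groups become wildcard atoms unless a
nearby ``R = Me``-style definition resolves them; coordinative bonds are
written to the Molfile as bond type 9 but have no SMILES representation and
are therefore dropped from the SMILES perception), and emits the two
renderings every molecule carries: a V2000 Molfile (``mdl``) and a
canonical SMILES (``cano_smiles``).

Stereochemistry enters only through wedge/hash bond displays: the drawing
coordinates plus wedge codes are written into the Molfile and perception is
delegated to RDKit's molblock reader, so a stereocenter drawn without a
wedge stays undefined in the SMILES — exactly the drawn information, no
more.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.rdBase import BlockLogs

from .errors import MoleculeError
from .library import Libraries, SuperatomEntry, resolve_superatom
from .model import BondDisplay, FragmentShape, NodeKind, Rect

log = logging.getLogger(__name__)

_PT = Chem.GetPeriodicTable()


@dataclass
class TableAtom:
    """One row of the chemistry table (post-expansion)."""

    symbol: str  # "*" for wildcards
    x: float
    y: float
    charge: int = 0
    isotope: int | None = None


@dataclass
class TableBond:
    begin: int  # 0-based atom indices
    end: int
    order: int | str = 1  # 1,2,3,"aromatic"
    wedge: int = 0  # Molfile stereo code: 0 none, 1 wedge, 6 hash
    coordinative: bool = False


@dataclass
class Molecule:
    """Chemistry-table form of one structure with both renderings.

    ``bbox`` keeps the drawing-coordinate extent for role assignment."""

    atoms: list[TableAtom]
    bonds: list[TableBond]
    cano_smiles: str
    mdl: str
    label: str | None = None
    description: str | None = None
    bbox: Rect | None = None
    fragment_id: int | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def has_coordinative_bond(self) -> bool:
        return any(b.coordinative for b in self.bonds)


# ---------------------------------------------------------------- expansion


@dataclass
class _WorkAtom:
    symbol: str
    x: float
    y: float
    charge: int = 0
    isotope: int | None = None


class _Work:
    """Mutable atom/bond table keyed by integer handles during expansion."""

    def __init__(self) -> None:
        self.atoms: dict[int, _WorkAtom] = {}
        self.bonds: list[dict] = []  # {begin, end, order, wedge, coordinative}
        self._next = 0

    def add_atom(self, atom: _WorkAtom) -> int:
        h = self._next
        self._next += 1
        self.atoms[h] = atom
        return h

    def neighbors(self, h: int) -> list[dict]:
        return [b for b in self.bonds if b["begin"] == h or b["end"] == h]


def expand_abbreviation(work: _Work, node: int, entry: SuperatomEntry) -> bool:
    """Replace atom handle ``node`` by the entry's expansion, grafting at the
    dummy-atom markers (ordered by map index).  Returns False (leaving the
    node untouched) when the node degree does not match the attachment
    count."""
    external = work.neighbors(node)
    if len(external) != entry.attachment_count:
        return False
    with BlockLogs():
        exp = Chem.MolFromSmiles(entry.expansion)
    pos = work.atoms[node]
    handle_of: dict[int, int] = {}
    dummies: list[Chem.Atom] = []
    for atom in exp.GetAtoms():
        if atom.GetAtomicNum() == 0:
            dummies.append(atom)
            continue
        k = len(handle_of)
        handle_of[atom.GetIdx()] = work.add_atom(_WorkAtom(
            symbol=atom.GetSymbol(),
            x=pos.x + 0.1 * (k + 1),
            y=pos.y + 0.07 * (k + 1),
            charge=atom.GetFormalCharge(),
            isotope=atom.GetIsotope() or None,
        ))
    for bond in exp.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i not in handle_of or j not in handle_of:
            continue
        order: int | str
        bt = bond.GetBondType()
        order = {Chem.BondType.SINGLE: 1, Chem.BondType.DOUBLE: 2,
                 Chem.BondType.TRIPLE: 3,
                 Chem.BondType.AROMATIC: "aromatic"}.get(bt, 1)
        work.bonds.append({"begin": handle_of[i], "end": handle_of[j],
                           "order": order, "wedge": 0, "coordinative": False})
    dummies.sort(key=lambda a: (a.GetAtomMapNum(), a.GetIdx()))
    for k, dummy in enumerate(dummies):
        graft = handle_of[dummy.GetNeighbors()[0].GetIdx()]
        ext = external[k]
        side = "begin" if ext["begin"] == node else "end"
        ext[side] = graft
    del work.atoms[node]
    return True


# -------------------------------------------------------------- renderings


_ORDER_TO_MOLFILE = {1: 1, 2: 2, 3: 3, "aromatic": 4}


def _molfile_from_table(atoms: list[TableAtom], bonds: list[TableBond],
                        scale: float, include_coordinative: bool = True,
                        name: str = "") -> str:
    """V2000 connection table; coordinative bonds as the nonstandard type 9.

    Drawing coordinates are rescaled so the median bond is 1.5 units and the
    y axis is flipped to the Molfile's y-up convention."""
    if not atoms:
        raise MoleculeError("empty molecule")
    if len(atoms) > 999:
        raise MoleculeError(
            f"{len(atoms)} atoms exceed the V2000 limit; V3000 is not supported")
    out_bonds = bonds if include_coordinative else \
        [b for b in bonds if not b.coordinative]
    lines = [name, "  chemscan 2D", "",
             f"{len(atoms):3d}{len(out_bonds):3d}  0  0  0  0  0  0  0  0999 V2000"]
    for a in atoms:
        x, y = a.x * scale, -a.y * scale
        lines.append(f"{x:10.4f}{y:10.4f}{0.0:10.4f} {a.symbol:<3s}"
                     " 0  0  0  0  0  0  0  0  0  0  0  0")
    for b in out_bonds:
        btype = 9 if b.coordinative else _ORDER_TO_MOLFILE[b.order]
        lines.append(f"{b.begin + 1:3d}{b.end + 1:3d}{btype:3d}{b.wedge:3d}")
    charged = [(i, a.charge) for i, a in enumerate(atoms) if a.charge]
    for start in range(0, len(charged), 8):
        chunk = charged[start:start + 8]
        lines.append("M  CHG" + f"{len(chunk):3d}" +
                     "".join(f"{i + 1:4d}{c:4d}" for i, c in chunk))
    isotopes = [(i, a.isotope) for i, a in enumerate(atoms) if a.isotope]
    for start in range(0, len(isotopes), 8):
        chunk = isotopes[start:start + 8]
        lines.append("M  ISO" + f"{len(chunk):3d}" +
                     "".join(f"{i + 1:4d}{m:4d}" for i, m in chunk))
    lines.append("M  END")
    return "\n".join(lines) + "\n"


def canonical_smiles_from_table(atoms: list[TableAtom], bonds: list[TableBond],
                                scale: float,
                                fragment_id: int | None = None) -> str:
    """Canonical SMILES of the table, coordinative bonds excluded (they have
    no SMILES representation).  Raises :class:`MoleculeError` carrying the
    fragment id when the molecule cannot be sanitized."""
    block = _molfile_from_table(atoms, bonds, scale, include_coordinative=False)
    with BlockLogs():
        mol = Chem.MolFromMolBlock(block)
    if mol is None:
        raise MoleculeError("molecule failed sanitization", fragment_id)
    return Chem.MolToSmiles(mol)


def to_molfile(m: Molecule) -> str:
    return m.mdl


def canonical_smiles(m: Molecule) -> str:
    return m.cano_smiles


# ------------------------------------------------------------------- build


def build_molecule(
    f: FragmentShape,
    libs: Libraries,
    rgroup_defs: dict[str, str] | None = None,
    median_bond_length: float | None = None,
) -> Molecule:
    """Turn one drawn fragment into a Molecule.

    ``rgroup_defs`` maps R-group labels to superatom keys harvested from
    nearby ``R = Me``-style texts; a well-defined R is substituted, any
    other R-group becomes a wildcard atom (``*``).  An abbreviation with no
    library hit also degrades to a wildcard with a warning — never fatal.
    """
    rgroup_defs = rgroup_defs or {}
    warnings: list[str] = []
    work = _Work()
    handle_by_id: dict[int, int] = {}
    for a in f.atoms:
        symbol = "*" if a.node_kind in (NodeKind.ABBREVIATION, NodeKind.R_GROUP,
                                        NodeKind.UNKNOWN) \
            else _PT.GetElementSymbol(a.element)
        handle_by_id[a.id] = work.add_atom(_WorkAtom(
            symbol=symbol, x=a.position.x, y=a.position.y,
            charge=a.charge, isotope=a.isotope))
    wedge_code = {BondDisplay.WEDGE: 1, BondDisplay.HASH: 6}
    for b in f.bonds:
        work.bonds.append({
            "begin": handle_by_id[b.begin], "end": handle_by_id[b.end],
            "order": b.order, "wedge": wedge_code.get(b.display, 0),
            "coordinative": b.display == BondDisplay.DATIVE,
        })

    for a in f.atoms:
        entry = None
        if a.node_kind == NodeKind.ABBREVIATION and a.label:
            entry = resolve_superatom(a.label, libs)
            if entry is None:
                warnings.append(f"abbreviation {a.label!r} not in library; "
                                "kept as wildcard")
        elif a.node_kind == NodeKind.R_GROUP and a.label in rgroup_defs:
            entry = resolve_superatom(rgroup_defs[a.label], libs)
        if entry is not None:
            if not expand_abbreviation(work, handle_by_id[a.id], entry):
                warnings.append(
                    f"abbreviation {a.label!r} drawn with "
                    f"{len(work.neighbors(handle_by_id[a.id]))} bonds but "
                    f"{entry.attachment_count} attachment(s); kept as wildcard")

    # freeze handles into a dense table
    order = sorted(work.atoms)
    index = {h: i for i, h in enumerate(order)}
    atoms = [TableAtom(symbol=work.atoms[h].symbol, x=work.atoms[h].x,
                       y=work.atoms[h].y, charge=work.atoms[h].charge,
                       isotope=work.atoms[h].isotope) for h in order]
    bonds = [TableBond(begin=index[b["begin"]], end=index[b["end"]],
                       order=b["order"], wedge=b["wedge"],
                       coordinative=b["coordinative"]) for b in work.bonds]

    mbl = median_bond_length
    if mbl is None:
        import math
        lengths = sorted(
            math.hypot(atoms[b.begin].x - atoms[b.end].x,
                       atoms[b.begin].y - atoms[b.end].y) for b in bonds)
        mbl = lengths[len(lengths) // 2] if lengths else 30.0
    scale = 1.5 / mbl if mbl > 0 else 1.0

    mdl = _molfile_from_table(atoms, bonds, scale)
    smiles = canonical_smiles_from_table(atoms, bonds, scale, f.id)
    for w in warnings:
        log.warning("fragment %d: %s", f.id, w)
    return Molecule(atoms=atoms, bonds=bonds, cano_smiles=smiles, mdl=mdl,
                    bbox=f.bbox if f.atoms else None, fragment_id=f.id,
                    warnings=warnings)
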