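"""2-D placement of molecules into drawings.

RDKit generates depiction coordinates (and wedge assignments for drawn
stereo); the resulting connection table is transcribed into the writable
drawing model at the editor's customary 30-point bond length, flipping to
the drawing's y-down convention.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.rdBase import BlockLogs

from .drawing import DrawnAtom, DrawnBond, DrawnFragment, DrawnText

_PT = Chem.GetPeriodicTable()


class IdAlloc:
    def __init__(self, start: int = 1):
        self._next = start

    def __call__(self) -> int:
        v = self._next
        self._next += 1
        return v


@dataclass
class Placed:
    """A drawn fragment plus its extent in drawing coordinates."""

    fragment: DrawnFragment
    min_x: float
    min_y: float
    max_x: float
    max_y: float

    @property
    def width(self) -> float:
        return self.max_x - self.min_x

    @property
    def height(self) -> float:
        return self.max_y - self.min_y

    @property
    def center_y(self) -> float:
        return (self.min_y + self.max_y) / 2


_ORDER_FROM_MOLFILE = {1: 1, 2: 2, 3: 3, 4: "aromatic"}
_DISPLAY_FROM_WEDGE = {0: "plain", 1: "wedge", 6: "hash"}


def mol_to_placed(
    mol_or_smiles: Chem.Mol | str,
    ids: IdAlloc,
    anchor_x: float,
    center_y: float,
    bond_length: float = 30.0,
    jitter=None,
) -> Placed:
    """Depict one molecule with its left edge at ``anchor_x`` and its
    vertical center at ``center_y``.

    ``jitter``, when given, is a callable returning a (dx, dy) perturbation
    per atom (used by the fixture generator for coordinate noise)."""
    if isinstance(mol_or_smiles, str):
        with BlockLogs():
            mol = Chem.MolFromSmiles(mol_or_smiles)
        if mol is None:
            raise ValueError(f"unparsable SMILES {mol_or_smiles!r}")
    else:
        mol = Chem.Mol(mol_or_smiles)
    AllChem.Compute2DCoords(mol)
    block = Chem.MolToMolBlock(mol, kekulize=True)
    lines = block.split("\n")
    natoms = int(lines[3][0:3])
    nbonds = int(lines[3][3:6])
    scale = bond_length / 1.5  # RDKit depicts at 1.5-unit bonds

    raw: list[tuple[float, float, str]] = []
    for i in range(natoms):
        line = lines[4 + i]
        x, y = float(line[0:10]), float(line[10:20])
        raw.append((x * scale, -y * scale, line[31:34].strip()))
    min_x = min(x for x, _, _ in raw)
    min_y = min(y for _, y, _ in raw)
    max_y = max(y for _, y, _ in raw)
    dx = anchor_x - min_x
    dy = center_y - (min_y + max_y) / 2

    charges: dict[int, int] = {}
    isotopes: dict[int, int] = {}
    for line in lines[4 + natoms + nbonds:]:
        if line.startswith("M  CHG") or line.startswith("M  ISO"):
            target = charges if line[3:6] == "CHG" else isotopes
            n = int(line[6:9])
            for k in range(n):
                idx = int(line[9 + 8 * k: 13 + 8 * k]) - 1
                target[idx] = int(line[13 + 8 * k: 17 + 8 * k])
        elif line.startswith("M  END"):
            break

    frag = DrawnFragment(id=ids())
    atom_ids: list[int] = []
    for i, (x, y, symbol) in enumerate(raw):
        jx, jy = jitter() if jitter else (0.0, 0.0)
        element = 6 if symbol == "*" else _PT.GetAtomicNumber(symbol)
        frag.atoms.append(DrawnAtom(
            id=ids(), x=x + dx + jx, y=y + dy + jy, element=element,
            charge=charges.get(i, 0), isotope=isotopes.get(i),
            label="R" if symbol == "*" else None,
            kind="r_group" if symbol == "*" else "element"))
        atom_ids.append(frag.atoms[-1].id)
    for i in range(nbonds):
        line = lines[4 + natoms + i]
        a1, a2 = int(line[0:3]) - 1, int(line[3:6]) - 1
        btype, stereo = int(line[6:9]), int(line[9:12])
        frag.bonds.append(DrawnBond(
            id=ids(), begin=atom_ids[a1], end=atom_ids[a2],
            order=_ORDER_FROM_MOLFILE.get(btype, 1),
            display=_DISPLAY_FROM_WEDGE.get(stereo, "plain")))

    xs = [a.x for a in frag.atoms]
    ys = [a.y for a in frag.atoms]
    return Placed(frag, min(xs), min(ys), max(xs), max(ys))


def make_text(ids: IdAlloc, value: str, cx: float, cy: float) -> DrawnText:
    return DrawnText(id=ids(), value=value, cx=cx, cy=cy)
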