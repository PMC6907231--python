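import random

import pytest
from rdkit import Chem

from chemscan.builder import (
    Molecule,
    TableAtom,
    _molfile_from_table,
    build_molecule,
    to_molfile,
)
from chemscan.cdxml_reader import parse_cdxml
from chemscan.drawing import (
    Drawing,
    DrawnAtom,
    DrawnBond,
    DrawnFragment,
    to_cdxml,
)
from chemscan.errors import MoleculeError
from chemscan.layout import IdAlloc
from chemscan.library import resolve_superatom

from conftest import ring_drawing


def graft_onto_benzene(expansion: str) -> str:
    """Independent oracle: RDKit-level graft of an expansion SMILES onto a
    benzene carbon (no chemscan code path involved)."""
    exp = Chem.MolFromSmiles(expansion)
    combo = Chem.RWMol(Chem.CombineMols(Chem.MolFromSmiles("c1ccccc1"), exp))
    dummy = next(a.GetIdx() for a in combo.GetAtoms() if a.GetAtomicNum() == 0)
    neighbor = combo.GetAtomWithIdx(dummy).GetNeighbors()[0].GetIdx()
    combo.AddBond(0, neighbor, Chem.BondType.SINGLE)
    combo.RemoveAtom(dummy)
    return Chem.MolToSmiles(combo.GetMol())


def build_from_ring(libs, **kwargs) -> Molecule:
    g = parse_cdxml(to_cdxml(ring_drawing(**kwargs)))
    return build_molecule(g.fragments[0], libs)


class TestBuildMolecule:
    def test_benzene(self, libs):
        m = build_from_ring(libs)
        assert m.cano_smiles == Chem.CanonSmiles("c1ccccc1")

    @pytest.mark.parametrize("label", ["OMe", "Boc", "Ts", "NMe2", "CF3"])
    def test_drawn_vs_expanded_oracle(self, libs, label):
        """An abbreviated drawing equals the fully drawn structure."""
        m = build_from_ring(libs, node_kind="abbreviation", node_label=label)
        entry = resolve_superatom(label, libs)
        assert m.cano_smiles == graft_onto_benzene(entry.expansion)

    def test_undefined_r_group_is_single_wildcard(self, libs):
        m = build_from_ring(libs, node_kind="r_group", node_label="R")
        assert m.cano_smiles.count("*") == 1

    def test_unknown_abbreviation_degrades_to_wildcard(self, libs):
        m = build_from_ring(libs, node_kind="abbreviation", node_label="Qzz")
        assert "*" in m.cano_smiles
        assert any("Qzz" in w for w in m.warnings)

    def test_degree_mismatch_leaves_wildcard(self, libs):
        """OMe drawn with two bonds cannot take a one-point expansion."""
        m = build_from_ring(libs, node_kind="abbreviation", node_label="OMe",
                            node_bonds=2)
        assert "*" in m.cano_smiles
        assert any("attachment" in w for w in m.warnings)

    def test_rgroup_definition_substituted(self, libs):
        g = parse_cdxml(to_cdxml(ring_drawing(node_kind="r_group",
                                              node_label="R")))
        m = build_molecule(g.fragments[0], libs, rgroup_defs={"R": "Me"})
        assert m.cano_smiles == Chem.CanonSmiles("Cc1ccccc1")

    def test_canonical_under_renumbering(self, libs):
        d = ring_drawing(node_kind="abbreviation", node_label="OMe")
        rng = random.Random(4)
        smiles = set()
        for _ in range(5):
            frag = d.fragments[0]
            rng.shuffle(frag.atoms)
            rng.shuffle(frag.bonds)
            g = parse_cdxml(to_cdxml(d))
            smiles.add(build_molecule(g.fragments[0], libs).cano_smiles)
        assert len(smiles) == 1

    def test_charges_and_isotopes_carried(self, libs):
        ids = IdAlloc()
        d = Drawing()
        f = DrawnFragment(id=ids())
        f.atoms.append(DrawnAtom(id=ids(), x=0, y=0, element=8, charge=-1,
                                 isotope=18))
        d.fragments.append(f)
        g = parse_cdxml(to_cdxml(d))
        m = build_molecule(g.fragments[0], libs)
        assert m.cano_smiles == "[18OH-]"


class TestStereo:
    def _propanol_fragment(self, wedge: str):
        ids = IdAlloc()
        d = Drawing()
        f = DrawnFragment(id=ids())
        # 2-butanol skeleton drawn flat; stereo only via the wedge display
        pts = [(0, 0), (26, -15), (52, 0), (78, -15), (26, -45)]
        elems = [6, 6, 6, 6, 8]
        for (x, y), z in zip(pts, elems):
            f.atoms.append(DrawnAtom(id=ids(), x=x, y=y, element=z))
        a = [atom.id for atom in f.atoms]
        f.bonds.append(DrawnBond(id=ids(), begin=a[0], end=a[1]))
        f.bonds.append(DrawnBond(id=ids(), begin=a[1], end=a[2]))
        f.bonds.append(DrawnBond(id=ids(), begin=a[2], end=a[3]))
        f.bonds.append(DrawnBond(id=ids(), begin=a[1], end=a[4],
                                 display=wedge))
        d.fragments.append(f)
        return d

    def test_wedge_encodes_stereocenter(self, libs):
        g = parse_cdxml(to_cdxml(self._propanol_fragment("wedge")))
        m = build_molecule(g.fragments[0], libs)
        assert "@" in m.cano_smiles

    def test_without_wedge_stereocenter_stays_undefined(self, libs):
        g = parse_cdxml(to_cdxml(self._propanol_fragment("plain")))
        m = build_molecule(g.fragments[0], libs)
        assert "@" not in m.cano_smiles
        assert m.cano_smiles == Chem.CanonSmiles("CCC(C)O")


class TestMolfile:
    def test_benzene_counts_line(self, libs):
        m = build_from_ring(libs)
        counts = to_molfile(m).splitlines()[3]
        assert counts.startswith("  6  6")

    def test_dative_bond_written_as_type_9_and_absent_from_smiles(self, libs):
        ids = IdAlloc()
        d = Drawing()
        f = DrawnFragment(id=ids())
        f.atoms.append(DrawnAtom(id=ids(), x=0, y=0, element=7))
        f.atoms.append(DrawnAtom(id=ids(), x=30, y=0, element=46))
        f.atoms.append(DrawnAtom(id=ids(), x=-30, y=0))
        a = [atom.id for atom in f.atoms]
        f.bonds.append(DrawnBond(id=ids(), begin=a[0], end=a[1],
                                 display="dative"))
        f.bonds.append(DrawnBond(id=ids(), begin=a[2], end=a[0]))
        d.fragments.append(f)
        g = parse_cdxml(to_cdxml(d))
        m = build_molecule(g.fragments[0], libs)
        bond_lines = m.mdl.splitlines()[4 + 3: 4 + 3 + 2]
        assert any(line[6:9] == "  9" for line in bond_lines)
        assert m.cano_smiles == Chem.CanonSmiles("CN.[Pd]")

    def test_molfile_roundtrip_through_independent_reader(self, libs):
        """Re-parsing the emitted Molfile reproduces cano_smiles."""
        for label in (None, "OMe", "Boc"):
            kwargs = {} if label is None else \
                {"node_kind": "abbreviation", "node_label": label}
            m = build_from_ring(libs, **kwargs)
            mol = Chem.MolFromMolBlock(m.mdl)
            assert Chem.MolToSmiles(mol) == m.cano_smiles

    def test_empty_molecule_is_error(self):
        with pytest.raises(MoleculeError):
            _molfile_from_table([], [], 1.0)

    def test_v2000_atom_limit(self):
        atoms = [TableAtom("C", float(i), 0.0) for i in range(1000)]
        with pytest.raises(MoleculeError, match="V3000"):
            _molfile_from_table(atoms, [], 1.0)
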