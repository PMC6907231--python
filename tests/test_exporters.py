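import shutil
import subprocess

import pytest
from rdkit import Chem

from chemscan.assembler import ReactionStep
from chemscan.builder import TableAtom, TableBond, Molecule
from chemscan.errors import ChemScanError
from chemscan.exporters import (
    reaction_smiles,
    write_cdxml,
    write_cml,
    write_json,
    write_table,
)
from chemscan.fixtures import generate_scheme, random_spec
from chemscan.pipeline import scan_bytes


def mol(smiles: str) -> Molecule:
    rd = Chem.MolFromSmiles(smiles)
    atoms = [TableAtom(a.GetSymbol(), float(i), 0.0, a.GetFormalCharge())
             for i, a in enumerate(rd.GetAtoms())]
    order = {Chem.BondType.SINGLE: 1, Chem.BondType.DOUBLE: 2,
             Chem.BondType.TRIPLE: 3, Chem.BondType.AROMATIC: "aromatic"}
    bonds = [TableBond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
                       order[b.GetBondType()]) for b in rd.GetBonds()]
    return Molecule(atoms=atoms, bonds=bonds,
                    cano_smiles=Chem.MolToSmiles(rd), mdl="")


class TestReactionSmiles:
    def test_no_agents(self):
        step = ReactionStep(reactants=[mol("CCO")], products=[mol("CC=O")])
        assert reaction_smiles(step) == "CCO>>CC=O"

    def test_with_agent(self):
        step = ReactionStep(reactants=[mol("CCO")], products=[mol("CC=O")],
                            solvents_smiles=["O"])
        assert reaction_smiles(step) == "CCO>O>CC=O"

    def test_two_reactants_drawing_order(self):
        step = ReactionStep(reactants=[mol("CCO"), mol("CC(=O)O")],
                            products=[mol("CCOC(C)=O")])
        assert reaction_smiles(step).split(">")[0] == "CCO.CC(=O)O"

    def test_empty_step_is_error(self):
        with pytest.raises(ChemScanError):
            reaction_smiles(ReactionStep())

    def test_components_reparse_canonical(self, libs):
        cdxml, _ = generate_scheme(random_spec(8))
        steps = scan_bytes(cdxml.encode(), "x", libs=libs)[0].steps
        for step in steps:
            for part in reaction_smiles(step).split(">"):
                for comp in filter(None, part.split(".")):
                    assert Chem.CanonSmiles(comp) == comp


class TestCml:
    def test_zero_steps_valid_document(self):
        from lxml import etree

        doc = etree.fromstring(write_cml([]).encode())
        assert doc.tag.endswith("cml")

    def test_yield_scalar_present(self):
        step = ReactionStep(reactants=[mol("CCO")], products=[mol("CC=O")],
                            yield_percent=95.0)
        assert ">95<" in write_cml([step])

    def test_independent_reader_recovers_molecules(self, libs, tmp_path):
        """openbabel re-parses the CML to the same canonical SMILES set."""
        if shutil.which("obabel") is None:
            pytest.skip("openbabel not on PATH")
        cdxml, _ = generate_scheme(random_spec(2, jitter=0.0))
        steps = scan_bytes(cdxml.encode(), "x", libs=libs)[0].steps
        path = tmp_path / "out.cml"
        path.write_text(write_cml(steps), encoding="utf-8")
        run = subprocess.run(["obabel", str(path), "-osmi"],
                             capture_output=True, text=True, timeout=120)
        got = {Chem.CanonSmiles(line.split()[0])
               for line in run.stdout.splitlines() if line.strip()}
        want = {m.cano_smiles for s in steps
                for m in s.reactants + s.products + s.reagents}
        assert got == want


class TestCdxmlExport:
    @pytest.mark.parametrize("seed", [5, 6, 9, 12, 18])
    def test_reextraction_identity(self, libs, seed):
        """Exported CDXML re-extracts to identical steps (roles, SMILES,
        conditions, status)."""
        cdxml, _ = generate_scheme(random_spec(seed))
        steps = scan_bytes(cdxml.encode(), "x", libs=libs)[0].steps
        out = write_cdxml(steps, libs)
        steps2 = scan_bytes(out.encode(), "re", libs=libs)[0].steps

        def key(ss):
            return [(sorted(m.cano_smiles for m in s.reactants),
                     sorted(m.cano_smiles for m in s.products),
                     sorted(s.agents_smiles), sorted(s.solvents_smiles),
                     s.time, s.temperature, s.yield_percent, s.status)
                    for s in ss]

        assert key(steps2) == key(steps)

    def test_molecule_only_export(self, libs):
        out = write_cdxml([mol("c1ccccc1")], libs)
        result = scan_bytes(out.encode(), "m", libs=libs)[0]
        assert result.steps == []
        assert [m.cano_smiles for m in result.molecules] == ["c1ccccc1"]

    def test_crossed_status_serialized(self, libs):
        step = ReactionStep(reactants=[mol("CCO")], products=[mol("CC=O")],
                            status="failed")
        out = write_cdxml([step], libs)
        assert 'NoGo="Cross"' in out
        steps2 = scan_bytes(out.encode(), "re", libs=libs)[0].steps
        assert steps2[0].status == "failed"


class TestTable:
    def test_row_count(self):
        steps = [ReactionStep(reactants=[mol("CCO")], products=[mol("CC=O")]),
                 ReactionStep(reactants=[mol("CCN")], products=[mol("CC=O")])]
        lines = write_table(steps, "csv").decode().strip().splitlines()
        assert len(lines) == 3

    def test_comma_in_description_quoted(self):
        step = ReactionStep(reactants=[mol("CCO")], products=[mol("CC=O")],
                            description="slow addition, then warm")
        text = write_table([step], "csv").decode()
        assert '"slow addition, then warm"' in text

    def test_empty_steps_header_only(self):
        lines = write_table([], "csv").decode().strip().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("reaction_smiles,")

    def test_spreadsheet_grid_matches_csv(self, tmp_path):
        from openpyxl import load_workbook
        import io

        steps = [ReactionStep(reactants=[mol("CCO")], products=[mol("CC=O")],
                              yield_percent=88.0)]
        data = write_table(steps, "spreadsheet")
        ws = load_workbook(io.BytesIO(data)).active
        assert ws.max_row == 2
        assert ws.cell(2, 1).value == "CCO>>CC=O"


def test_json_export_shape(libs):
    cdxml, _ = generate_scheme(random_spec(4, jitter=0.0))
    steps = scan_bytes(cdxml.encode(), "x", libs=libs)[0].steps
    import json

    doc = json.loads(write_json(steps))
    assert len(doc["reactions"]) == len(steps)
    assert {"reactants", "products", "status"} <= set(doc["reactions"][0])
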