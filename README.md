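# chemscan

Extraction of molecules and role-assigned single-step reactions from
ChemDraw drawings — native CDX (binary) and CDXML (XML) files and the
documents that embed them (DOC, DOCX, ELN-export XML) — with export to
reaction SMILES, Molfile, CML, CDXML and tabular formats.

Chemists document most synthetic work as ChemDraw schemes embedded in Word
files or saved as native drawings. The chemistry in those files — structures,
reaction arrows, reagents scribbled over the arrow, times, temperatures,
yields — is machine-readable in principle but locked in a proprietary object
model. `chemscan` parses that object model and reconstructs the chemistry:

* **Molecules.** Every drawn fragment becomes a chemistry table with two
  renderings: a canonical SMILES (`cano_smiles`, via RDKit) and a V2000
  Molfile (`mdl`). Superatom abbreviations ("OMe", "Boc", "Ts", …) are
  expanded through a curated label→SMILES library; trivial names and
  formulas in text ("DMF", "NEt₃") resolve through a name library with
  internal-over-editor priority. R-groups become wildcard atoms `*` unless a
  nearby `R = Me`-style text defines them; coordinative bonds are written to
  the Molfile as bond type 9 (they have no SMILES representation);
  stereochemistry enters only through wedge/hash bonds.
* **Reactions.** Roles follow the drawing's geometry: for each arrow, every
  object's bounding-box center is projected onto the arrow axis — left of
  the tail are reactants, right of the head products, and a band above/below
  the arrow holds reagents, solvents (classified against a solvent library)
  and condition text (time, temperature, yield). Multistep schemes are split
  into single-step reactions `reactants > agents > products`; a crossed
  arrow flags a failed reaction, a dashed one a planned reaction.
* **Containers.** DOCX (zip), DOC (OLE compound file) and ELN-export XML are
  unwrapped; ELN reaction tables are reconciled against the drawn scheme on
  canonical SMILES.

## Worked example

```python
from chemscan import load_libraries, scan_bytes
from chemscan.fixtures import SchemeSpec, StepSpec, generate_scheme

spec = SchemeSpec(steps=[StepSpec(
    reactants=["CCO", "CC(=O)O"], product="CCOC(C)=O",
    solvent="THF", reagents_text=["NEt3"],
    temperature=(80.0, "°C"), time=(12.0, "h"), yield_percent=85.0)],
    jitter=0.05, seed=7)
cdxml, _ = generate_scheme(spec)          # a synthetic drawing
result = scan_bytes(cdxml.encode(), "example", libs=load_libraries())[0]
step = result.steps[0]
print([m.cano_smiles for m in step.reactants], "->",
      [m.cano_smiles for m in step.products])
print(step.solvents_smiles, step.reagents_smiles,
      step.temperature, step.time, step.yield_percent, step.status)
```

prints

```
['CCO', 'CC(=O)O'] -> ['CCOC(C)=O']
['C1CCOC1'] ['CCN(CC)CC'] Quantity(value=80.0, unit='°C') Quantity(value=12.0, unit='h') 85.0 success
```

i.e. ethanol + acetic acid give ethyl acetate; THF was recognized from the
band text and classified as the solvent, triethylamine as a reagent; the
conditions and yield were parsed from the text over the arrow, and the plain
arrow marks the reaction successful. The `examples/` directory holds one
short script per capability (scheme scanning, superatom expansion, embedded
documents, ELN reconciliation, exports).

A thin CLI wraps the same pipeline:

```bash
chemscan scan scheme.cdxml --out csv
chemscan extract-embedded thesis.doc --out payloads/
chemscan fixtures --seed 1 --count 5 --out fixtures/
```

## Layout

```
src/chemscan/      library (readers, libraries, builder, assembler,
                   text interpreter, exporters, fixture generator, CLI)
src/chemscan/data/ seed superatom/name/solvent/reagent libraries (TSV)
tests/             pytest suite
examples/          narrative scripts, one per capability
docs/methods.md    model, geometry rules, parameters, limitations
```
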