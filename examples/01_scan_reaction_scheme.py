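"""Scan a reaction scheme drawing and print the extracted single steps.

Builds a small two-step CDXML scheme with the in-repo generator (so the
example needs no external files), runs the extraction pipeline and prints
each step's role groups, conditions and status.
"""

from chemscan import load_libraries, scan_bytes
from chemscan.fixtures import SchemeSpec, StepSpec, generate_scheme

spec = SchemeSpec(steps=[
    StepSpec(reactants=["CCO", "CC(=O)O"], product="CCOC(C)=O",
             solvent="THF", reagents_text=["NEt3"],
             temperature=(80.0, "°C"), time=(12.0, "h"), yield_percent=85.0),
    StepSpec(reactants=["CCOC(C)=O"], product="CC(=O)O",
             solvent="DMF", arrow_style="dashed"),
], layout="wrapped-chain", jitter=0.05, seed=7)

cdxml, _truth = generate_scheme(spec)
libs = load_libraries()
result = scan_bytes(cdxml.encode(), "example.cdxml", libs=libs)[0]

for step in result.steps:
    print(f"step {step.step_index} [{step.status}]")
    print("  reactants:", [m.cano_smiles for m in step.reactants])
    print("  agents:   ", step.agents_smiles)
    print("  solvents: ", step.solvents_smiles)
    print("  products: ", [m.cano_smiles for m in step.products])
    print("  T:", step.temperature, " t:", step.time,
          " yield:", step.yield_percent)

# The two steps chain: the ester product of step 1 is the reactant of the
# (dashed = planned) hydrolysis in step 2; conditions come from the text
# written around each arrow.
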