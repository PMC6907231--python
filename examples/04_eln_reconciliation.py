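"""Cross-check an ELN-export XML: drawn scheme vs. reaction table.

The ELN dialect carries a CDXML island plus a tabular list of the
chemicals.  Reconciliation compares both on canonical SMILES and reports
what is present on only one side.
"""

from chemscan import load_libraries, scan_bytes
from chemscan.containers import ElnReactionRecord
from chemscan.fixtures import SchemeSpec, StepSpec, generate_scheme, \
    wrap_in_container

libs = load_libraries()
spec = SchemeSpec(steps=[StepSpec(reactants=["CCO"], product="CC=O",
                                  solvent="THF")], jitter=0.0)
cdxml, _ = generate_scheme(spec)

records = [ElnReactionRecord("reactant", "CCO", amounts="2 mmol"),
           ElnReactionRecord("solvent", "THF", amounts="5 mL"),
           ElnReactionRecord("product", "CC=O"),
           ElnReactionRecord("solvent", "DMSO")]  # not in the drawing!

eln = wrap_in_container(cdxml.encode(), "eln_xml", records=records)
result = scan_bytes(eln, "export.xml", libs=libs)[0]

print("table rows:", [(r.role, r.identifier) for r in result.records])
print("scheme steps:", len(result.steps))
for d in result.discrepancies:
    print("discrepancy:", d.kind, "-", d.identifier)

# DMSO appears in the table but nowhere in the drawing, so reconciliation
# flags exactly one "missing-in-scheme" entry; everything else matches.
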