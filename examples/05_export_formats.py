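"""Export extracted reactions: reaction SMILES, CSV, CML and CDXML.

The CDXML export is round-trippable: re-scanning the exported drawing
reproduces the same steps.
"""

from chemscan import load_libraries, scan_bytes
from chemscan.exporters import (
    reaction_smiles,
    write_cdxml,
    write_cml,
    write_table,
)
from chemscan.fixtures import generate_scheme, random_spec

libs = load_libraries()
cdxml, _ = generate_scheme(random_spec(2, jitter=0.0))
steps = scan_bytes(cdxml.encode(), "scheme", libs=libs)[0].steps

print("reaction SMILES:")
for step in steps:
    print(" ", reaction_smiles(step))

csv_text = write_table(steps, "csv").decode()
print(f"\nCSV: {len(csv_text.splitlines())} lines"
      f" (header + {len(steps)} step rows)")

cml = write_cml(steps)
print(f"CML: {len(cml)} characters,"
      f" {cml.count('<molecule')} molecule tables")

exported = write_cdxml(steps, libs)
again = scan_bytes(exported.encode(), "reexport", libs=libs)[0].steps
same = [sorted(m.cano_smiles for m in s.products) for s in steps] == \
       [sorted(m.cano_smiles for m in s.products) for s in again]
print(f"CDXML re-extraction reproduces the products: {same}")
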