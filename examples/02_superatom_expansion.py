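"""Expand superatom abbreviations ("OMe", "Boc", "Ts" ...) while building
molecules.

A drawing where a benzene carbon carries the single node "Boc" must yield
the same canonical SMILES as the fully drawn tert-butoxycarbonyl benzene.
"""

from chemscan import load_libraries, resolve_superatom, scan_bytes
from chemscan.fixtures import abbreviation_scheme

libs = load_libraries()
for label in ("OMe", "Boc", "Ts", "CF3", "NMe2"):
    entry = resolve_superatom(label, libs)
    cdxml = abbreviation_scheme(label)
    molecule = scan_bytes(cdxml.encode(), label, libs=libs)[0].molecules[0]
    print(f"{label:>5s}  expansion={entry.expansion:<28s}"
          f" drawn scheme → {molecule.cano_smiles}")

# Each line shows the library expansion (with its [*] attachment marker)
# and the canonical SMILES extracted from a scheme that used only the
# abbreviated node — the expansion has been grafted onto the ring.
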