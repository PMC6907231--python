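"""Extract ChemDraw payloads embedded in DOC and DOCX documents.

Wraps a CDX drawing into both container formats, then recovers it
byte-identically and runs the extraction pipeline on the result.
"""

from chemscan import extract_from_doc, extract_from_docx, load_libraries, \
    scan_bytes
from chemscan.fixtures import generate_scheme_cdx, random_spec, \
    wrap_in_container

libs = load_libraries()
cdx, _truth = generate_scheme_cdx(random_spec(3, jitter=0.0))

for kind, extract in (("docx", extract_from_docx), ("doc", extract_from_doc)):
    container = wrap_in_container(cdx, kind)
    payloads = extract(container)
    print(f"{kind}: container {len(container)} bytes →"
          f" {len(payloads)} payload(s),"
          f" byte-identical={payloads[0].data == cdx},"
          f" origin={payloads[0].origin}")
    steps = scan_bytes(container, kind, libs=libs)[0].steps
    print(f"      extracted {len(steps)} reaction step(s)")

# Both containers give back the exact CDX bytes that were embedded, and
# scanning the container directly is equivalent to scanning the bare file.
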