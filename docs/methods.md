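# Methods

## The extraction model

A ChemDraw drawing is a tree of objects (pages, fragments, nodes, bonds,
text, graphics) with typed properties. `chemscan` reduces it to a
`SchemeGraph`: chemical fragments with atom coordinates, text blocks with
bounding boxes, and arrows with tail/head points and a style flag. Both
dialects feed the same model — the CDXML reader walks the XML, the CDX
reader walks the binary tag-length-value tree (little-endian, 32-bit
fixed-point coordinates divided by 65536, 2-D positions stored y-before-x,
strings carrying a style-run header). Only the ~20 properties extraction
needs are decoded; unknown elements and tags are skip-logged, never fatal.
Object ids are remapped into one fresh namespace per graph so several
payloads from one document can coexist.

Coordinates are drawing "points" with **y growing downward**; "above the
arrow" therefore means smaller y. All downstream decisions are invariant
under translation and positive uniform scaling of the drawing (widths that
matter are expressed in arrow lengths or median bond lengths), which the
test suite asserts directly.

## Molecule building

Fragments become molecules through a single path: the atom/bond table
(after superatom expansion) is written to a V2000 Molfile — coordinates
rescaled so the *median drawn bond* is 1.5 units, y flipped to the
Molfile's y-up convention — and RDKit's molblock reader performs valence,
aromaticity and stereo perception. Consequences, all deliberate:

* stereo exists in the SMILES only where a wedge/hash bond encodes it; a
  stereocenter drawn flat stays undefined;
* drawn alternating single/double rings and explicit aromatic bond orders
  canonicalize identically;
* coordinative (dative) bonds appear in the Molfile as the nonstandard bond
  type 9 but are removed before SMILES perception — SMILES has no
  representation for them, so a dative complex renders as disconnected
  components;
* implicit hydrogens follow standard valence rules; explicit H nodes are
  preserved through perception.

Superatom expansion grafts the library expansion (dummy-atom attachment
markers, ordered by atom-map index for multi-point groups) at the node's
neighbors, preserving the drawn bond order. A node whose degree does not
match the entry's attachment count, or whose label misses the library,
degrades to a wildcard atom with a warning — never a hard failure. An
abbreviation node that carries its own inner fragment (an editor-expanded
nickname) uses that drawn expansion and skips the library: the drawing is
ground truth. R-group nodes become wildcards unless a text block of the
form `R = <label>` resolves `<label>` as a superatom; any other definition
style (e.g. a drawn aryl with locants) intentionally leaves the wildcard.

## Libraries

Four dictionaries in a plain TSV format (`key<TAB>smiles[<TAB>source]`,
`#` comments): superatoms, names, solvents, reagents. The shipped seeds
(≈40 superatoms, ≈80 names, 17 solvents, ≈27 reagents) are small curated
subsets; the loader accepts full-size files in the same format. Name lookup
tries exact case, then case-insensitive, then with `./,` stripped; when one
key maps to several structures, internal entries outrank corpus entries,
which outrank editor-derived ones. Entries with unparsable SMILES are
dropped and counted; the seeds load with zero warnings. Every seed
superatom passes a drawn-vs-expanded oracle (abbreviated drawing ==
independently grafted full structure).

Solvent-vs-reagent classification is pure set membership of the canonical
SMILES in the solvent dictionary — the list is configurable because no
canonical solvent roster exists; the seed covers ~17 common lab solvents.

## Role assignment geometry

For an arrow with tail **T** and head **H**, an object's bounding-box
center projects to `(t, d)`: `t` the normalized position along T→H, `d` the
signed perpendicular distance (negative above a left-to-right arrow). Zones:

| zone | condition | default widths |
|------|-----------|----------------|
| reactant | `t < 0`, `abs(d) ≤ side` | `side = max(5 × median bond, band)` |
| product | `t > 1`, `abs(d) ≤ side` | same |
| band (reagents/solvents/conditions) | `−0.15 ≤ t ≤ 1.15`, `abs(d) ≤ band` | `band = min(0.6 × arrow length, 4 × median bond)` |

Objects outside all zones are left for other arrows; leftovers are reported
as isolated molecules — nothing is silently dropped. The projected
formulation handles vertical and diagonal arrows without special cases.
The margins are configuration (`AssemblerConfig`), chosen once to be
generous at typical drawing densities; the source conventions only say "a
certain area above or below the arrow".

When several arrows claim one fragment, claims are resolved **per role** by
distance to the arrow *segment* (perpendicular distance alone cannot
discriminate between collinear arrows in a one-row chain). A product claim
from one arrow plus a reactant claim from another survive together — that
double membership *is* the multistep chain link. Any combination involving
a band claim keeps only the nearest arrow. Texts never chain, so the
nearest claim always wins.

Chains are built from three link rules: a shared fragment
(product-of-*i* ∩ reactant-of-*j*), head-to-tail adjacency within 0.75
arrow lengths, and — for wrapped layouts that redraw the intermediate —
equal canonical SMILES between reading-order-adjacent arrows (best-effort:
a deliberately re-used structure between unrelated adjacent arrows would
over-link). The arrow digraph is ordered topologically (Kahn); a cycle is a
hard error. One `ReactionStep` is emitted per arrow with a chain-local
`step_index`; steps missing a side are flagged `incomplete`, not dropped.

Within the band, drawn fragments become reagent molecules; texts go through
the interpreter: name-library hits (then raw-SMILES parsing of formula-like
tokens) become compounds, split solvent-vs-reagent by the solvent set;
time/temperature/yield tokens merge into the step; unmatched text is kept
as the step description. A known ambiguity inherited from the drawing
convention itself: a new co-reactant introduced mid-chain ("+ C" between
two arrows) is geometrically indistinguishable from a second product of the
previous step, so generated test schemes introduce co-reactants only on the
first step of one-row chains (wrapped layouts are unaffected — their rows
are farther apart than any zone).

## Text interpretation

The token grammar is data-driven (`data/patterns.cfg`): time units
(s/min/h/d plus synonyms), temperature units (°C, K) and qualitative tokens
(rt, reflux, overnight), yield as a trailing `%` token with an optional
"yield:" prefix. Tokens are comma/semicolon-separated; a comma flanked by
digits is treated as a decimal comma (European documents), not a separator.
Classification never loses text — every token ends up as a compound, a
parsed condition, or residue — and a render→parse property test holds over
the whole fixture grammar. Compound labels use a conservative heuristic:
a token matching `^\d+[a-z]?$` whose center sits within 1.5 median bond
lengths below a fragment is attached to that molecule as its label.
"overnight" stays a qualitative token; mapping it to a number would invent
data.

## Exports

Reaction SMILES is `reactants>agents>products` with dot-joined canonical
components (agents = drawn band reagents + text reagents + solvents). CML
gets full atom/bond tables per molecule plus scalar properties for
conditions; the reaction status is a named property since CML has no
standard outcome field. CDXML export regenerates layout on a fixed grid
(30-point bonds, 90-point arrows, band text 20 points below the axis,
drawn reagents centered 45 points above it, one row per step) chosen so
re-extraction through the normal pipeline is the identity on roles, SMILES,
conditions and status; this is asserted against the fixture corpus, and
the CML export is cross-checked with OpenBabel as an independent reader.
CSV is RFC-4180; the spreadsheet variant writes the same grid.

Export layout regenerates coordinates from canonical SMILES, so molecules
whose only distinguishing feature is a coordinative bond do not survive a
CDXML export round trip (SMILES cannot carry them) — consistent with the
documented SMILES limitation.

## Synthetic fixtures: what they emulate and what they do not

The generator renders seeded schemes — 1–4 steps, 1–3 reactants, 0–3 band
members (drawn reagents, text reagents, solvent), conditions, yields,
plain/dashed/crossed arrows — in three arrangements (one-row chain, wrapped
chain, vertical) with bounded coordinate jitter (≤ 10 % of a bond length,
small enough that no object crosses a zone boundary; an adversarial test
pushes jitter beyond that and asserts only determinism). Ground truth is
recorded at generation time, and byte-determinism per seed is asserted.
Containers are generated too: DOCX as a minimal OPC zip with an OLE-wrapped
`CONTENTS` stream, DOC via an in-repo minimal OLE compound-file writer
(512-byte sectors, FAT + mini-FAT, header DIFAT), ELN-XML with a CDXML
island and a reaction table.

What passing these tests shows: the geometry logic, both dialect readers,
expansion, text interpretation, chain splitting and every exporter are
mutually consistent and match ground truth under realistic layout noise.
What it does not show: robustness to the full variety of hand-drawn
real-world schemes (curved arrows, stoichiometry grids, exotic arrangement
styles, editor-version serialization quirks) — the generator emits one
writer's dialect, and real editor files exercise many more object types,
which the readers skip-log rather than interpret.

## Numerical and degenerate-input choices

Zero-length arrows are skipped at parse time; an empty molecule or a
>999-atom fragment (V2000 limit) is a `MoleculeError`; an unsanitizable
fragment is reported with its fragment id and excluded without aborting the
scheme. Median bond length falls back to 30 points for bond-less drawings.
CDXML coordinates are written with 2-decimal precision and CDX with 1/65536
fixed point; both are far below any decision margin, and dialect parity is
asserted over the fixture corpus. An 8-byte CDX file containing only the
magic parses as an empty scheme. Equilibrium/retrosynthesis arrows are not
distinguished from plain arrows.

## Known limitations

* R-groups other than well-defined `R = <superatom>` lose information (a
  wildcard `*` remains).
* Coordinative bonds exist only in the Molfile rendering (type 9).
* Stereo requires wedges; carbohydrate-style implicit stereo is lost.
* Curved/multi-head arrows, electron pushing, polymer brackets, V3000
  Molfiles and 3-D coordinates are out of scope.
* The ELN-XML field mapping ships only for the in-repo dialect; other
  exporters' dialects need a mapping configuration.
* The full curated libraries are external data; the seeds are
  representative subsets in the same format.
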