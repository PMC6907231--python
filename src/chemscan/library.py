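"""Superatom, name→SMILES, solvent and reagent dictionaries.

File format: UTF-8 TSV, ``key<TAB>smiles[<TAB>source]``, ``#`` comments.
Superatom expansions mark their attachment point(s) with dummy atoms
(``[*]`` or ``[*:1]``, ``[*:2]``, … for multi-point grafting, ordered by
map index).

Lookup rules: exact-case match first, then case-insensitive; name lookup
additionally retries with ``.``/``,`` stripped.  When a key exists with
several sources, the internal entry takes priority over corpus entries,
which take priority over editor-derived (Name=Struct) ones.

The shipped seed libraries are small curated subsets in the same format the
full curated dictionaries use; the loader accepts full-size files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from rdkit import Chem
from rdkit.rdBase import BlockLogs

from .errors import ChemScanError

log = logging.getLogger(__name__)

_SOURCE_PRIORITY = {"internal": 0, "corpus": 1, "editor": 2}


def canonicalize(smiles: str) -> str | None:
    """Canonical SMILES via RDKit, or None when unparsable."""
    with BlockLogs():
        mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class SuperatomEntry:
    key: str
    expansion: str  # SMILES with dummy-atom attachment markers
    attachment_count: int


@dataclass(frozen=True)
class NameEntry:
    key: str
    smiles: str  # canonical
    source: str = "internal"


@dataclass
class Libraries:
    superatoms: dict[str, SuperatomEntry] = field(default_factory=dict)
    names: dict[str, list[NameEntry]] = field(default_factory=dict)
    solvents: set[str] = field(default_factory=set)  # canonical SMILES
    reagents: list[tuple[str, str]] = field(default_factory=list)
    warnings: int = 0


def _iter_tsv(path: Path):
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        yield lineno, line.split("\t")


def _normalize_key(key: str) -> str:
    return " ".join(key.split())


def _data_path(name: str) -> Path:
    return Path(str(resources.files("chemscan").joinpath("data", name)))


def load_libraries(
    superatoms: str | Path | None = None,
    names: str | Path | None = None,
    solvents: str | Path | None = None,
    reagents: str | Path | None = None,
) -> Libraries:
    """Load the four dictionaries; ``None`` falls back to the shipped seeds.

    Entries whose SMILES does not parse are dropped with a warning (counted
    in ``Libraries.warnings``); the shipped seed files load with zero
    warnings.  A missing explicitly named file raises."""
    libs = Libraries()

    def resolve(arg, default_name) -> Path:
        if arg is None:
            return _data_path(default_name)
        p = Path(arg)
        if not p.exists():
            raise ChemScanError(f"library file not found: {p}")
        return p

    for lineno, fieldsv in _iter_tsv(resolve(superatoms, "superatoms.tsv")):
        if len(fieldsv) < 2:
            log.warning("superatom line %d malformed, dropped", lineno)
            libs.warnings += 1
            continue
        key, expansion = _normalize_key(fieldsv[0]), fieldsv[1]
        with BlockLogs():
            mol = Chem.MolFromSmiles(expansion)
        if mol is None:
            log.warning("superatom %r has unparsable expansion, dropped", key)
            libs.warnings += 1
            continue
        count = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 0)
        if count < 1:
            log.warning("superatom %r has no attachment marker, dropped", key)
            libs.warnings += 1
            continue
        libs.superatoms[key] = SuperatomEntry(key, expansion, count)

    for lineno, fieldsv in _iter_tsv(resolve(names, "names.tsv")):
        if len(fieldsv) < 2:
            log.warning("name line %d malformed, dropped", lineno)
            libs.warnings += 1
            continue
        key = _normalize_key(fieldsv[0])
        cano = canonicalize(fieldsv[1])
        if cano is None:
            log.warning("name %r has unparsable SMILES, dropped", key)
            libs.warnings += 1
            continue
        source = fieldsv[2] if len(fieldsv) > 2 else "internal"
        libs.names.setdefault(key, []).append(NameEntry(key, cano, source))

    for lineno, fieldsv in _iter_tsv(resolve(solvents, "solvents.tsv")):
        cano = canonicalize(fieldsv[-1])
        if cano is None:
            log.warning("solvent line %d unparsable, dropped", lineno)
            libs.warnings += 1
            continue
        libs.solvents.add(cano)

    for lineno, fieldsv in _iter_tsv(resolve(reagents, "reagents.tsv")):
        if len(fieldsv) < 2:
            log.warning("reagent line %d malformed, dropped", lineno)
            libs.warnings += 1
            continue
        cano = canonicalize(fieldsv[1])
        if cano is None:
            log.warning("reagent %r unparsable, dropped", fieldsv[0])
            libs.warnings += 1
            continue
        libs.reagents.append((_normalize_key(fieldsv[0]), cano))

    for entries in libs.names.values():
        entries.sort(key=lambda e: _SOURCE_PRIORITY.get(e.source, 3))
    return libs


def resolve_superatom(label: str, libs: Libraries) -> SuperatomEntry | None:
    """Exact-match lookup; on miss retry with leading/trailing hyphens
    stripped, then case-insensitively."""
    label = _normalize_key(label)
    for candidate in (label, label.strip("-‐‑")):
        if candidate in libs.superatoms:
            return libs.superatoms[candidate]
    lowered = label.strip("-‐‑").lower()
    for key, entry in libs.superatoms.items():
        if key.lower() == lowered:
            return entry
    return None


def resolve_name(text: str, libs: Libraries) -> str | None:
    """Name → canonical SMILES.

    Priority within one key: internal, then corpus, then editor entries —
    the first hit wins.  Exact-case lookup first, then case-insensitive,
    then with ``.`` and ``,`` stripped."""
    key = _normalize_key(text)
    if not key:
        return None
    entries = libs.names.get(key)
    if entries:
        return entries[0].smiles
    lowered = key.lower()
    for k, v in libs.names.items():
        if k.lower() == lowered:
            return v[0].smiles
    stripped = key.replace(".", "").replace(",", "").strip()
    if stripped and stripped != key:
        return resolve_name(stripped, libs)
    return None


def classify_smiles_role(smiles: str, libs: Libraries) -> str:
    """``"solvent"`` iff the canonical form is in the solvent set, else
    ``"reagent"``.  Raises for unparsable SMILES."""
    cano = canonicalize(smiles)
    if cano is None:
        raise ChemScanError(f"unparsable SMILES {smiles!r}")
    return "solvent" if cano in libs.solvents else "reagent"
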