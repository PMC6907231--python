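"""Classification of scheme text blocks.

Free text in a drawing is one of: a compound (trivial name, abbreviation or
formula resolvable to a structure), reaction conditions (time, temperature,
yield), a compound label ("13a" under a structure), or residual
description.  The token grammar — units, qualitative tokens, separators —
is data-driven (``data/patterns.cfg``) so it can be extended without code
changes; decimal commas are accepted alongside decimal points.

Classification never loses text: every token of the input ends up as a
resolved compound, a parsed condition, or residue.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from rdkit import Chem
from rdkit.rdBase import BlockLogs

from .library import Libraries, resolve_name
from .model import FragmentShape, TextBlock

__all__ = ["Quantity", "ConditionSet", "TextClassification", "PatternTable",
           "parse_conditions", "classify_text_block", "extract_yield"]


@dataclass(frozen=True)
class Quantity:
    value: float
    unit: str


@dataclass
class ConditionSet:
    time: Quantity | str | None = None  # Quantity or qualitative token
    temperature: Quantity | str | None = None
    yield_percent: float | None = None
    residue: list[str] = field(default_factory=list)

    def is_empty(self) -> bool:
        return (self.time is None and self.temperature is None
                and self.yield_percent is None and not self.residue)

    def merge(self, other: "ConditionSet") -> None:
        if self.time is None:
            self.time = other.time
        if self.temperature is None:
            self.temperature = other.temperature
        if self.yield_percent is None:
            self.yield_percent = other.yield_percent
        self.residue.extend(other.residue)


@dataclass
class TextClassification:
    """Outcome for one text block.

    ``kind`` reports the dominant content; a block like "NaH, 0 °C" yields
    both a compound and a condition, so the compound list and the condition
    set are carried side by side and jointly account for every token."""

    kind: str  # compound | condition | label | unknown
    raw: str
    smiles: list[str] = field(default_factory=list)
    conditions: ConditionSet = field(default_factory=ConditionSet)
    label: str | None = None


class PatternTable:
    """Token grammar loaded from a key/value config file."""

    def __init__(self, path: str | Path | None = None):
        cfg: dict[str, list[str]] = {}
        if path is None:
            path = Path(str(resources.files("chemscan").joinpath(
                "data", "patterns.cfg")))
        for raw in Path(path).read_text(encoding="utf-8").splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            cfg[key.strip()] = value.split()
        self.time_units = cfg.get("time_units", ["s", "min", "h", "d"])
        self.time_qualitative = [t.lower() for t in
                                 cfg.get("time_qualitative", ["overnight"])]
        self.temp_units = cfg.get("temp_units", ["°C", "C", "K"])
        self.temp_qualitative = [t.lower() for t in
                                 cfg.get("temp_qualitative", ["rt", "reflux"])]
        self.yield_prefixes = [t.lower() for t in
                               cfg.get("yield_prefixes", ["yield", "yield:"])]
        self.separators = cfg.get("separators", [",", ";"])

        number = r"(-?\d+(?:[.,]\d+)?)"
        units = "|".join(re.escape(u) for u in
                         sorted(self.time_units, key=len, reverse=True))
        self._time_re = re.compile(rf"^{number}\s*({units})$")
        temp_units = "|".join(re.escape(u) for u in
                              sorted(self.temp_units, key=len, reverse=True))
        self._temp_re = re.compile(rf"^{number}\s*°?\s*({temp_units})$")
        self._yield_re = re.compile(rf"^{number}\s*%$")

    @staticmethod
    def _num(token: str) -> float:
        return float(token.replace(",", "."))

    _CANONICAL_TIME = {"sec": "s", "secs": "s", "hr": "h", "hrs": "h",
                       "hour": "h", "hours": "h", "day": "d", "days": "d",
                       "mins": "min"}

    def match_token(self, token: str) -> tuple[str, object] | None:
        """Classify one comma-separated token.

        Returns (field, value) where field is ``time``/``temperature``/
        ``yield`` — or None when the token is not a condition."""
        token = token.strip()
        m = self._temp_re.match(token)
        if m:
            unit = m.group(2)
            return "temperature", Quantity(self._num(m.group(1)),
                                           "°C" if unit in ("C", "°C") else unit)
        m = self._time_re.match(token)
        if m:
            unit = self._CANONICAL_TIME.get(m.group(2), m.group(2))
            return "time", Quantity(self._num(m.group(1)), unit)
        lowered = token.lower()
        if lowered in self.temp_qualitative:
            return "temperature", "rt" if lowered in ("rt", "r.t.") else lowered
        if lowered in self.time_qualitative:
            return "time", lowered
        for prefix in sorted(self.yield_prefixes, key=len, reverse=True):
            if lowered.startswith(prefix):
                token = token[len(prefix):].lstrip(" :=").strip()
                lowered = token.lower()
                break
        m = self._yield_re.match(token)
        if m:
            value = self._num(m.group(1))
            if 0.0 <= value <= 100.0:
                return "yield", value
        return None


_DEFAULT_TABLE: PatternTable | None = None


def default_table() -> PatternTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = PatternTable()
    return _DEFAULT_TABLE


def _split(text: str, table: PatternTable) -> list[str]:
    # a comma flanked by digits is a decimal comma, not a separator
    parts = []
    for s in table.separators:
        if s == ",":
            parts.append(r",(?!\d)|(?<!\d),")
        else:
            parts.append(re.escape(s))
    return [t.strip() for t in re.split("|".join(parts), text) if t.strip()]


def parse_conditions(text: str, table: PatternTable | None = None) -> ConditionSet:
    """Scan separator-delimited tokens against the pattern table.

    Always returns (possibly empty); unmatched tokens land in ``residue``."""
    table = table or default_table()
    out = ConditionSet()
    for token in _split(text, table):
        hit = table.match_token(token)
        if hit is None:
            out.residue.append(token)
        elif hit[0] == "time" and out.time is None:
            out.time = hit[1]
        elif hit[0] == "temperature" and out.temperature is None:
            out.temperature = hit[1]
        elif hit[0] == "yield" and out.yield_percent is None:
            out.yield_percent = hit[1]
        else:
            out.residue.append(token)
    return out


LABEL_PATTERN = re.compile(r"^\d+[a-z]?$")


def _try_smiles(token: str) -> str | None:
    """Accept a token as a raw SMILES formula only when it is not a plain
    word (avoids reading names like "CO" as SMILES — the name library has
    priority anyway)."""
    if LABEL_PATTERN.match(token) or token in ("+", "-"):
        return None
    if re.fullmatch(r"[A-Za-z]{1,2}", token):
        return None
    with BlockLogs():
        mol = Chem.MolFromSmiles(token)
    if mol is None or mol.GetNumAtoms() == 0:
        return None
    return Chem.MolToSmiles(mol)


def classify_text_block(
    t: TextBlock,
    libs: Libraries,
    fragments: list[FragmentShape] | None = None,
    median_bond_length: float = 30.0,
    table: PatternTable | None = None,
) -> TextClassification:
    """Classify one text block.

    Attempt order: whole-string name lookup; token-wise name lookup / raw
    SMILES / condition patterns; label heuristic (short alphanumeric token
    sitting just below a fragment); else unknown with the raw preserved."""
    table = table or default_table()
    raw = t.value
    whole = resolve_name(raw, libs)
    if whole is not None:
        return TextClassification(kind="compound", raw=raw, smiles=[whole])

    smiles: list[str] = []
    conditions = ConditionSet()
    residue: list[str] = []
    for token in _split(raw, table):
        hit_name = resolve_name(token, libs)
        if hit_name is not None:
            smiles.append(hit_name)
            continue
        hit_cond = table.match_token(token)
        if hit_cond is not None:
            field_, value = hit_cond
            if field_ == "time" and conditions.time is None:
                conditions.time = value
            elif field_ == "temperature" and conditions.temperature is None:
                conditions.temperature = value
            elif field_ == "yield" and conditions.yield_percent is None:
                conditions.yield_percent = value
            else:
                residue.append(token)
            continue
        hit_smiles = _try_smiles(token)
        if hit_smiles is not None:
            smiles.append(hit_smiles)
            continue
        residue.append(token)
    conditions.residue = residue

    if smiles:
        return TextClassification(kind="compound", raw=raw, smiles=smiles,
                                  conditions=conditions)
    if conditions.time is not None or conditions.temperature is not None \
            or conditions.yield_percent is not None:
        return TextClassification(kind="condition", raw=raw,
                                  conditions=conditions)

    if fragments and LABEL_PATTERN.match(raw.strip()):
        center = t.bbox.center
        for f in fragments:
            if not f.atoms:
                continue
            fb = f.bbox
            below = center.y - fb.max.y
            if 0.0 <= below <= 1.5 * median_bond_length and \
                    fb.min.x - median_bond_length <= center.x <= fb.max.x + median_bond_length:
                return TextClassification(kind="label", raw=raw,
                                          label=raw.strip())
    return TextClassification(kind="unknown", raw=raw, conditions=conditions)


def extract_yield(texts: list[TextBlock], table: PatternTable | None = None,
                  ) -> float | None:
    """First percentage token found in the given texts (band or
    product-adjacent); later conflicting duplicates are ignored."""
    table = table or default_table()
    for t in texts:
        for token in _split(t.value, table):
            hit = table.match_token(token)
            if hit is not None and hit[0] == "yield":
                return hit[1]
    return None
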