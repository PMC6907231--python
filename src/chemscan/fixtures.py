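"""Seeded synthetic-scheme generator with machine-readable ground truth.

Every pipeline stage is testable without external files: a
:class:`SchemeSpec` describes a reaction scheme (steps, band content,
conditions, arrow styles, layout arrangement, coordinate jitter), and
:func:`generate_scheme` renders it to CDXML (or CDX via
:func:`generate_scheme_cdx`) together with the :class:`GroundTruth` the
extraction pipeline must reproduce.  Output bytes are fully determined by
the spec's seed.

Layout arrangements: ``horizontal-chain`` draws the whole sequence on one
row sharing the intermediate molecules; ``wrapped-chain`` puts each step on
its own row, redrawing the intermediate (the common "scheme continues on
the next line" style); ``vertical`` stacks the steps top-to-bottom with
downward arrows.  Jitter is bounded (≤ 10 % of a bond length) so no object
crosses a zone boundary — robustness beyond that is probed separately by
adversarial tests that only assert determinism.
"""

from __future__ import annotations

import io
import random
import zipfile
from dataclasses import dataclass, field

from lxml import etree

from . import cfb
from .containers import ElnReactionRecord
from .drawing import Drawing, DrawnArrow, to_cdx, to_cdxml
from .errors import ChemScanError
from .layout import IdAlloc, make_text, mol_to_placed
from .library import canonicalize
from .textinterp import Quantity

BOND_LENGTH = 30.0
ARROW_LENGTH = 90.0
GAP = 22.0
BAND_OFFSET = 24.0
ROW_HEIGHT = 320.0


@dataclass
class StepSpec:
    reactants: list[str]  # SMILES, drawn
    product: str  # SMILES, drawn
    reagents_drawn: list[str] = field(default_factory=list)  # SMILES, drawn in band
    reagents_text: list[str] = field(default_factory=list)  # names, written in band
    solvent: str | None = None  # name, written in band
    time: tuple[float, str] | str | None = None
    temperature: tuple[float, str] | str | None = None
    yield_percent: float | None = None
    arrow_style: str = "plain"  # plain | dashed | crossed
    product_label: str | None = None


@dataclass
class SchemeSpec:
    steps: list[StepSpec]
    layout: str = "horizontal-chain"  # horizontal-chain | wrapped-chain | vertical
    jitter: float = 0.0  # noise amplitude as fraction of bond length
    seed: int = 0


@dataclass
class StepTruth:
    reactants: list[str]
    products: list[str]
    reagents_drawn: list[str]
    reagents_text: list[str]
    solvents: list[str]
    time: Quantity | str | None
    temperature: Quantity | str | None
    yield_percent: float | None
    status: str


@dataclass
class GroundTruth:
    steps: list[StepTruth]
    labels: dict[str, str] = field(default_factory=dict)  # cano_smiles → label

    def to_dict(self) -> dict:
        def q(v):
            if v is None or isinstance(v, str):
                return v
            return {"value": v.value, "unit": v.unit}

        return {"steps": [{
            "reactants": s.reactants, "products": s.products,
            "reagents_drawn": s.reagents_drawn,
            "reagents_text": s.reagents_text, "solvents": s.solvents,
            "time": q(s.time), "temperature": q(s.temperature),
            "yield": s.yield_percent, "status": s.status,
        } for s in self.steps], "labels": self.labels}


_STATUS = {"plain": "success", "dashed": "planned", "crossed": "failed"}

# names the seed library resolves; kept here so specs stay self-contained
_NAME_SMILES = {
    "THF": "C1CCOC1", "DMF": "CN(C)C=O", "toluene": "Cc1ccccc1",
    "EtOH": "CCO", "MeCN": "CC#N", "dioxane": "C1COCCO1",
    "NEt3": "CCN(CC)CC", "pyridine": "c1ccncc1", "DBU": "C1CCC2=NCCCN2CC1",
    "K2CO3": "O=C([O-])[O-].[K+].[K+]", "NaH": "[H-].[Na+]",
    "DMAP": "CN(C)c1ccncc1",
}


def _quantity(v: tuple[float, str] | str | None) -> Quantity | str | None:
    if v is None or isinstance(v, str):
        return v
    return Quantity(v[0], v[1])


def _render_quantity(v: tuple[float, str] | str) -> str:
    if isinstance(v, str):
        return v
    value, unit = v
    return f"{value:g} {unit}"


def _band_text(step: StepSpec) -> str | None:
    tokens: list[str] = []
    tokens.extend(step.reagents_text)
    if step.solvent:
        tokens.append(step.solvent)
    if step.temperature is not None:
        tokens.append(_render_quantity(step.temperature))
    if step.time is not None:
        tokens.append(_render_quantity(step.time))
    if step.yield_percent is not None:
        tokens.append(f"{step.yield_percent:g}%")
    return ", ".join(tokens) if tokens else None


def _truth_for(spec: SchemeSpec) -> GroundTruth:
    truth = GroundTruth(steps=[])
    for step in spec.steps:
        def cano(smiles: str) -> str:
            c = canonicalize(smiles)
            if c is None:
                raise ChemScanError(f"unparsable SMILES in spec: {smiles!r}")
            return c

        truth.steps.append(StepTruth(
            reactants=sorted(cano(s) for s in step.reactants),
            products=sorted([cano(step.product)]),
            reagents_drawn=sorted(cano(s) for s in step.reagents_drawn),
            reagents_text=sorted(cano(_NAME_SMILES[n])
                                 for n in step.reagents_text),
            solvents=sorted([cano(_NAME_SMILES[step.solvent])]
                            if step.solvent else []),
            time=_quantity(step.time),
            temperature=_quantity(step.temperature),
            yield_percent=step.yield_percent,
            status=_STATUS[step.arrow_style],
        ))
        if step.product_label:
            truth.labels[cano(step.product)] = step.product_label
    return truth


def build_drawing(spec: SchemeSpec) -> tuple[Drawing, GroundTruth]:
    """Render the spec to the writable drawing model (shared by the CDXML
    and CDX serializations so dialect parity holds by construction)."""
    rng = random.Random(spec.seed)
    amp = spec.jitter * BOND_LENGTH

    def jitter():
        if amp <= 0:
            return (0.0, 0.0)
        return (rng.uniform(-amp, amp), rng.uniform(-amp, amp))

    ids = IdAlloc()
    d = Drawing(bond_length=BOND_LENGTH)
    truth = _truth_for(spec)

    if spec.layout == "vertical":
        _layout_vertical(spec, d, ids, jitter)
    else:
        _layout_rows(spec, d, ids, jitter,
                     wrapped=(spec.layout == "wrapped-chain"))
    return d, truth


def _place_band(step: StepSpec, d: Drawing, ids: IdAlloc, jitter,
                mid_x: float, y: float, horizontal: bool = True) -> None:
    """Band content stays within the default band half-width (0.6 × arrow
    length): drawn reagents are *centered* 45 points off the axis and the
    condition text sits on the other side of the arrow."""
    if horizontal:
        for j, smi in enumerate(step.reagents_drawn):
            placed = mol_to_placed(smi, ids, mid_x - 28.0 + 34.0 * j,
                                   y - 45.0, BOND_LENGTH, jitter)
            # recenter horizontally on the requested slot
            shift = (mid_x - 6.0 + 34.0 * j) - (placed.min_x + placed.max_x) / 2
            for a in placed.fragment.atoms:
                a.x += shift
            d.fragments.append(placed.fragment)
        text = _band_text(step)
        if text:
            jx, jy = jitter()
            d.texts.append(make_text(ids, text, mid_x + jx, y + 28.0 + jy))
    else:  # vertical arrow: reagents left of the axis, tokens right
        for j, smi in enumerate(step.reagents_drawn):
            placed = mol_to_placed(smi, ids, mid_x - 90.0,
                                   y + 30.0 * j, BOND_LENGTH, jitter)
            shift = (mid_x - 45.0) - (placed.min_x + placed.max_x) / 2
            for a in placed.fragment.atoms:
                a.x += shift
            d.fragments.append(placed.fragment)
        text = _band_text(step)
        if text:
            tokens = [t.strip() for t in text.split(",")]
            span = ARROW_LENGTH * 0.8
            for j, token in enumerate(tokens):
                jx, jy = jitter()
                ty = y - span / 2 + (span * (j + 0.5) / len(tokens))
                d.texts.append(make_text(ids, token, mid_x + 35.0 + jx,
                                         ty + jy))


def _layout_rows(spec: SchemeSpec, d: Drawing, ids: IdAlloc, jitter,
                 wrapped: bool) -> None:
    y = 150.0
    x = 30.0
    for k, step in enumerate(spec.steps):
        if wrapped and k > 0:
            y += ROW_HEIGHT
            x = 30.0
        draw_reactants = step.reactants if (k == 0 or wrapped) \
            else step.reactants[1:]  # shared intermediate already drawn
        for i, smi in enumerate(draw_reactants):
            if i > 0 or (not wrapped and k > 0 and draw_reactants):
                jx, jy = jitter()
                d.texts.append(make_text(ids, "+", x + 4 + jx, y + jy))
                x += 20.0
            placed = mol_to_placed(smi, ids, x, y, BOND_LENGTH, jitter)
            d.fragments.append(placed.fragment)
            x = placed.max_x + GAP
        jx, jy = jitter()
        tail = (x + jx, y + jy)
        jx, jy = jitter()
        head = (x + ARROW_LENGTH + jx, y + jy)
        d.arrows.append(DrawnArrow(id=ids(), tail=tail, head=head,
                                   style=step.arrow_style))
        _place_band(step, d, ids, jitter, x + ARROW_LENGTH / 2, y)
        x = head[0] + GAP
        placed = mol_to_placed(step.product, ids, x, y, BOND_LENGTH, jitter)
        d.fragments.append(placed.fragment)
        if step.product_label:
            jx, jy = jitter()
            d.texts.append(make_text(
                ids, step.product_label,
                (placed.min_x + placed.max_x) / 2 + jx,
                placed.max_y + 18.0 + jy))
        x = placed.max_x + GAP


def _layout_vertical(spec: SchemeSpec, d: Drawing, ids: IdAlloc,
                     jitter) -> None:
    x = 200.0
    y = 80.0
    for k, step in enumerate(spec.steps):
        draw_reactants = step.reactants if k == 0 else step.reactants[1:]
        # co-reactants stack on the arrow axis so every center stays inside
        # the reactant zone of the downward arrow
        for i, smi in enumerate(draw_reactants):
            if i > 0:
                jx, jy = jitter()
                d.texts.append(make_text(ids, "+", x + 30.0 + jx, y + jy))
                y += 18.0
            placed = mol_to_placed(smi, ids, x, y + 45.0, BOND_LENGTH, jitter)
            shift = (x + 30.0) - (placed.min_x + placed.max_x) / 2
            for a in placed.fragment.atoms:
                a.x += shift
            d.fragments.append(placed.fragment)
            y = placed.max_y + GAP
        jx, jy = jitter()
        tail = (x + 30.0 + jx, y + jy)
        jx, jy = jitter()
        head = (x + 30.0 + jx, y + ARROW_LENGTH + jy)
        d.arrows.append(DrawnArrow(id=ids(), tail=tail, head=head,
                                   style=step.arrow_style))
        _place_band(step, d, ids, jitter, x + 30.0,
                    y + ARROW_LENGTH / 2, horizontal=False)
        y = head[1] + GAP
        placed = mol_to_placed(step.product, ids, x, y + 40.0, BOND_LENGTH,
                               jitter)
        shift = (x + 30.0) - (placed.min_x + placed.max_x) / 2
        for a in placed.fragment.atoms:
            a.x += shift
        d.fragments.append(placed.fragment)
        if step.product_label:
            jx, jy = jitter()
            d.texts.append(make_text(
                ids, step.product_label,
                (placed.min_x + placed.max_x) / 2 + jx,
                placed.max_y + 18.0 + jy))
        y = placed.max_y + GAP


def generate_scheme(spec: SchemeSpec) -> tuple[str, GroundTruth]:
    """CDXML text + ground truth; byte-deterministic for a fixed seed."""
    d, truth = build_drawing(spec)
    return to_cdxml(d), truth


def generate_scheme_cdx(spec: SchemeSpec) -> tuple[bytes, GroundTruth]:
    """Binary-dialect serialization of the same drawing."""
    d, truth = build_drawing(spec)
    return to_cdx(d), truth


def abbreviation_scheme(label: str) -> str:
    """CDXML drawing of a benzene ring carrying one abbreviation node.

    Used to test superatom expansion: extraction of this scheme must equal
    the canonical SMILES of the fully drawn structure."""
    import math

    ids = IdAlloc()
    d = Drawing(bond_length=BOND_LENGTH)
    from .drawing import DrawnAtom, DrawnBond, DrawnFragment

    frag = DrawnFragment(id=ids())
    cx, cy, r = 150.0, 150.0, BOND_LENGTH
    ring_ids = []
    for k in range(6):
        ang = math.radians(60 * k)
        frag.atoms.append(DrawnAtom(id=ids(), x=cx + r * math.cos(ang),
                                    y=cy + r * math.sin(ang)))
        ring_ids.append(frag.atoms[-1].id)
    for k in range(6):
        frag.bonds.append(DrawnBond(id=ids(), begin=ring_ids[k],
                                    end=ring_ids[(k + 1) % 6],
                                    order=2 if k % 2 == 0 else 1))
    frag.atoms.append(DrawnAtom(id=ids(), x=cx + 2 * r, y=cy,
                                label=label, kind="abbreviation"))
    frag.bonds.append(DrawnBond(id=ids(), begin=ring_ids[0],
                                end=frag.atoms[-1].id))
    d.fragments.append(frag)
    return to_cdxml(d)


def compare_to_truth(steps, truth: GroundTruth) -> list[str]:
    """Mismatches between extracted steps and the generator's ground truth
    (empty list = exact match on roles, SMILES, conditions, status)."""
    problems: list[str] = []
    if len(steps) != len(truth.steps):
        return [f"step count {len(steps)} != {len(truth.steps)}"]
    for k, (step, want) in enumerate(zip(steps, truth.steps), 1):
        def check(name: str, got, expected) -> None:
            if got != expected:
                problems.append(f"step {k} {name}: {got!r} != {expected!r}")

        check("reactants", sorted(m.cano_smiles for m in step.reactants),
              want.reactants)
        check("products", sorted(m.cano_smiles for m in step.products),
              want.products)
        check("reagents_drawn", sorted(m.cano_smiles for m in step.reagents),
              want.reagents_drawn)
        check("reagents_text", sorted(step.reagents_smiles),
              want.reagents_text)
        check("solvents", sorted(step.solvents_smiles), want.solvents)
        check("time", step.time, want.time)
        check("temperature", step.temperature, want.temperature)
        check("yield", step.yield_percent, want.yield_percent)
        check("status", step.status, want.status)
    got_labels = {}
    for step in steps:
        for m in step.reactants + step.products:
            if m.label:
                got_labels[m.cano_smiles] = m.label
    if got_labels != truth.labels:
        problems.append(f"labels {got_labels!r} != {truth.labels!r}")
    return problems


# ------------------------------------------------------------ random specs


DEFAULT_POOL = [
    "CCO", "CC=O", "c1ccccc1", "Cc1ccccc1", "Oc1ccccc1", "CC(=O)O",
    "CCN", "C1CCCCC1", "CC(C)=O", "Brc1ccccc1", "C[C@H](O)CC",
    "O=Cc1ccccc1", "CCOC(C)=O", "Nc1ccccc1", "c1ccncc1",
]

_REAGENT_DRAWN_POOL = ["CCN(CC)CC", "CN(C)c1ccncc1", "O=S(Cl)Cl"]
_REAGENT_TEXT_POOL = ["NEt3", "pyridine", "DBU", "K2CO3", "NaH", "DMAP"]
_SOLVENT_POOL = ["THF", "DMF", "toluene", "EtOH", "MeCN", "dioxane"]
_TIME_POOL = [(1.0, "h"), (12.0, "h"), (30.0, "min"), (2.0, "d"), "overnight"]
_TEMP_POOL = [(80.0, "°C"), (0.0, "°C"), (-78.0, "°C"), "rt", "reflux"]


def random_spec(
    seed: int,
    max_steps: int = 4,
    pool: list[str] | None = None,
    arrangement_weights: dict[str, float] | None = None,
    jitter: float | None = None,
) -> SchemeSpec:
    """Reproducible pseudo-random spec drawn from the molecule pool; arrow
    styles are sampled including crossed/dashed."""
    if pool is None:
        pool = DEFAULT_POOL
    if not pool:
        raise ChemScanError("molecule pool must not be empty")
    weights = arrangement_weights or {"horizontal-chain": 0.45,
                                      "wrapped-chain": 0.35, "vertical": 0.2}
    rng = random.Random(seed)
    k = rng.randint(1, max_steps)
    layout = rng.choices(list(weights), weights=list(weights.values()))[0]
    steps: list[StepSpec] = []
    prev_product: str | None = None
    available = list(pool)
    for i in range(k):
        co_allowed = (i == 0) or layout == "wrapped-chain"
        n_reactants = rng.randint(1, 3) if co_allowed else 1
        reactants = []
        if prev_product is not None:
            reactants.append(prev_product)
            n_reactants -= 1
        choices = [s for s in available if s != prev_product]
        reactants.extend(rng.sample(choices, max(n_reactants, 0)))
        product = rng.choice([s for s in choices if s not in reactants])
        band_budget = rng.randint(0, 3)
        reagents_drawn = [rng.choice(_REAGENT_DRAWN_POOL)] \
            if band_budget >= 3 else []
        reagents_text = rng.sample(_REAGENT_TEXT_POOL, min(band_budget, 2)) \
            if band_budget in (1, 2) else []
        solvent = rng.choice(_SOLVENT_POOL) if rng.random() < 0.6 else None
        steps.append(StepSpec(
            reactants=reactants,
            product=product,
            reagents_drawn=reagents_drawn,
            reagents_text=reagents_text,
            solvent=solvent,
            time=rng.choice(_TIME_POOL) if rng.random() < 0.6 else None,
            temperature=rng.choice(_TEMP_POOL) if rng.random() < 0.6 else None,
            yield_percent=float(rng.randint(10, 99))
            if rng.random() < 0.5 else None,
            arrow_style=rng.choices(["plain", "dashed", "crossed"],
                                    weights=[0.7, 0.15, 0.15])[0],
            product_label=f"{i + 1}a" if rng.random() < 0.25 else None,
        ))
        prev_product = product
    return SchemeSpec(steps=steps, layout=layout,
                      jitter=rng.uniform(0.0, 0.1) if jitter is None
                      else jitter,
                      seed=seed)


# --------------------------------------------------------------- containers


def wrap_in_container(
    payload: bytes | list[bytes],
    kind: str,
    records: list[ElnReactionRecord] | None = None,
) -> bytes:
    """Wrap payload bytes in a minimal standards-conforming container from
    which ``containers`` recovers them byte-identically.

    ``docx``/``doc`` expect CDX payload(s); ``eln_xml`` expects CDXML text
    and optionally reaction-table records."""
    payloads = payload if isinstance(payload, list) else [payload]
    if kind == "docx":
        buf = io.BytesIO()
        with zipfile.ZipFile(buf, "w", zipfile.ZIP_DEFLATED) as zf:
            def add(name: str, data: bytes) -> None:
                info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
                zf.writestr(info, data)

            add("[Content_Types].xml",
                b'<?xml version="1.0"?><Types xmlns="http://schemas.openxml'
                b'formats.org/package/2006/content-types"/>')
            add("word/document.xml",
                b'<?xml version="1.0"?><document/>')
            for i, p in enumerate(payloads, 1):
                ole = cfb.build({"CONTENTS": p})
                add(f"word/embeddings/oleObject{i}.bin", ole)
        return buf.getvalue()
    if kind == "doc":
        pool = {f"_{1000000000 + i}": {"CONTENTS": p}
                for i, p in enumerate(payloads, 1)}
        return cfb.build({
            "WordDocument": b"\x00" * 64,
            "ObjectPool": pool,
        })
    if kind == "eln_xml":
        root = etree.Element("eln")
        exp = etree.SubElement(root, "experiment")
        for p in payloads:
            scheme = etree.SubElement(exp, "scheme")
            island = etree.fromstring(p)
            scheme.append(island)
        table = etree.SubElement(exp, "reactionTable")
        for rec in records or []:
            row = etree.SubElement(table, "row", role=rec.role)
            for tag, value in (("identifier", rec.identifier),
                               ("amount", rec.amounts),
                               ("conditions", rec.conditions),
                               ("observation", rec.observations)):
                el = etree.SubElement(row, tag)
                el.text = value
        return etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                              pretty_print=True)
    raise ChemScanError(f"unknown container kind {kind!r}")
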