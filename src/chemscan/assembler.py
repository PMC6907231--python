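"""Geometry-driven reaction assembly.

Every object of a scheme is assigned a role *relative to an arrow* by
projecting its bounding-box center onto the arrow axis: beyond the tail is
the reactant side, beyond the head the product side, and a band of
configurable half-width straddling the arrow collects reagents, solvents
and condition text.  The formulation is fully projected — vertical and
diagonal arrows need no special casing — and role assignment is invariant
under translation and uniform scaling of the whole drawing.

Multi-arrow schemes are split into single-step reactions by chaining
arrows: a fragment sitting in the product zone of one arrow and the
reactant zone of another links the two steps (it appears in both), and
wrapped layouts that redraw the intermediate are linked by canonical-SMILES
identity between reading-order-adjacent arrows.  Cyclic arrow graphs are
rejected.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .builder import Molecule
from .errors import CyclicSchemeError
from .library import Libraries, classify_smiles_role
from .model import (
    ArrowShape,
    ArrowStyle,
    SchemeGraph,
    TextBlock,
    distance_to_segment,
    project_on_arrow,
)
from .textinterp import (
    ConditionSet,
    PatternTable,
    Quantity,
    classify_text_block,
    default_table,
)

log = logging.getLogger(__name__)


@dataclass
class AssemblerConfig:
    """Zone geometry defaults.

    The source drawings only say "a certain area above or below the arrow";
    these margins pin that down and are deliberately configurable.  Widths
    scale with the arrow and the drawing's median bond length so the same
    config works at any drawing scale."""

    band_frac: float = 0.6  # band half-width as fraction of arrow length
    band_cap_bonds: float = 4.0  # ... capped at this many median bond lengths
    axis_extension: float = 0.15  # band t-interval stretch beyond tail/head
    side_cap_bonds: float = 5.0  # side-zone half-width in median bond lengths
    chain_gap_frac: float = 0.75  # head-to-tail adjacency threshold
    label_dist_bonds: float = 1.5


@dataclass
class StepContext:
    """Role candidates for one arrow, in arrow-projected coordinates."""

    arrow: ArrowShape
    reactant_fragments: list[int] = field(default_factory=list)
    product_fragments: list[int] = field(default_factory=list)
    band_fragments: list[int] = field(default_factory=list)
    band_texts: list[int] = field(default_factory=list)
    reactant_texts: list[int] = field(default_factory=list)
    product_texts: list[int] = field(default_factory=list)


@dataclass
class ReactionStep:
    """One single-step reaction: the three molecule groups plus conditions,
    status and provenance.  ``reagents_smiles``/``solvents_smiles`` hold the
    text-identified band compounds (canonical SMILES)."""

    reactants: list[Molecule] = field(default_factory=list)
    reagents: list[Molecule] = field(default_factory=list)
    products: list[Molecule] = field(default_factory=list)
    reagents_smiles: list[str] = field(default_factory=list)
    solvents_smiles: list[str] = field(default_factory=list)
    time: Quantity | str | None = None
    temperature: Quantity | str | None = None
    yield_percent: float | None = None
    status: str = "unspecified"  # success | failed | planned | unspecified
    description: str = ""
    step_index: int = 1
    incomplete: bool = False
    arrow_id: int | None = None
    source: str = ""

    @property
    def agents_smiles(self) -> list[str]:
        return ([m.cano_smiles for m in self.reagents]
                + self.reagents_smiles + self.solvents_smiles)


def interpret_arrow_style(a: ArrowShape) -> str:
    """crossed → failed, dashed → planned, plain → success."""
    return {ArrowStyle.CROSSED: "failed",
            ArrowStyle.DASHED: "planned",
            ArrowStyle.PLAIN: "success"}[a.style]


def assign_roles(g: SchemeGraph, a: ArrowShape,
                 config: AssemblerConfig | None = None) -> StepContext:
    """Assign every fragment/text of the graph a role candidate for arrow
    ``a``; objects outside all zones are left for other arrows."""
    config = config or AssemblerConfig()
    mbl = g.median_bond_length()
    band_hw = min(config.band_frac * a.length, config.band_cap_bonds * mbl)
    side_hw = max(config.side_cap_bonds * mbl, band_hw)
    ctx = StepContext(arrow=a)

    def zone(t: float, d: float) -> str | None:
        if t < 0.0 and abs(d) <= side_hw:
            return "reactant"
        if t > 1.0 and abs(d) <= side_hw:
            return "product"
        if -config.axis_extension <= t <= 1.0 + config.axis_extension \
                and abs(d) <= band_hw:
            return "band"
        return None

    for f in g.fragments:
        if not f.atoms:
            continue
        z = zone(*project_on_arrow(f.bbox.center, a))
        if z == "reactant":
            ctx.reactant_fragments.append(f.id)
        elif z == "product":
            ctx.product_fragments.append(f.id)
        elif z == "band":
            ctx.band_fragments.append(f.id)
    for t in g.texts:
        z = zone(*project_on_arrow(t.bbox.center, a))
        if z == "reactant":
            ctx.reactant_texts.append(t.id)
        elif z == "product":
            ctx.product_texts.append(t.id)
        elif z == "band":
            ctx.band_texts.append(t.id)
    return ctx


def _reading_order(arrows: list[ArrowShape], mbl: float) -> list[ArrowShape]:
    """Document reading order: arrows clustered into rows (gap in y larger
    than 4 median bond lengths starts a new row — a *relative* criterion so
    the order is translation and scale invariant), rows top to bottom,
    left to right within a row."""
    if not arrows:
        return []
    by_y = sorted(arrows, key=lambda a: (min(a.tail.y, a.head.y), a.id))
    threshold = 4 * mbl
    rows: list[list[ArrowShape]] = [[by_y[0]]]
    row_y = min(by_y[0].tail.y, by_y[0].head.y)
    for a in by_y[1:]:
        y = min(a.tail.y, a.head.y)
        if y - row_y > threshold:
            rows.append([a])
        else:
            rows[-1].append(a)
        row_y = y
    out: list[ArrowShape] = []
    for row in rows:
        out.extend(sorted(row, key=lambda a: (min(a.tail.x, a.head.x), a.id)))
    return out


def _resolve_multiclaims(g: SchemeGraph, contexts: list[StepContext]) -> None:
    """Resolve objects claimed by several arrows.

    Fragments: claims are pruned *per role* — several arrows claiming the
    same fragment as (say) their product keep only the nearest claim
    (distance to the arrow segment), while a product claim from one arrow
    plus a reactant claim from another coexist: that double membership *is*
    the multistep chain link.  Texts never chain, so the nearest claim wins
    outright."""
    frag_center = {f.id: f.bbox.center for f in g.fragments if f.atoms}
    text_center = {t.id: t.bbox.center for t in g.texts}

    def prune(role: str, centers: dict) -> None:
        claims: dict[int, list[StepContext]] = {}
        for ctx in contexts:
            for oid in getattr(ctx, role):
                claims.setdefault(oid, []).append(ctx)
        for oid, holders in claims.items():
            if len(holders) < 2:
                continue
            best = min(holders,
                       key=lambda c: distance_to_segment(centers[oid], c.arrow))
            for ctx in holders:
                if ctx is not best:
                    getattr(ctx, role).remove(oid)

    for role in ("reactant_fragments", "product_fragments", "band_fragments"):
        prune(role, frag_center)

    # cross-role claims: only the product(i)/reactant(j) pair coexists (the
    # chain link); any combination involving a band claim keeps the nearest
    cross: dict[int, list[tuple[StepContext, str]]] = {}
    for ctx in contexts:
        for role in ("reactant_fragments", "product_fragments",
                     "band_fragments"):
            for oid in getattr(ctx, role):
                cross.setdefault(oid, []).append((ctx, role))
    for oid, holders in cross.items():
        if len(holders) < 2:
            continue
        role_names = {r for _, r in holders}
        if role_names == {"product_fragments", "reactant_fragments"}:
            continue
        best = min(holders,
                   key=lambda h: distance_to_segment(frag_center[oid],
                                                     h[0].arrow))
        for holder in holders:
            if holder is not best:
                getattr(holder[0], holder[1]).remove(oid)

    text_claims: dict[int, list[tuple[StepContext, str]]] = {}
    for ctx in contexts:
        for role in ("reactant_texts", "product_texts", "band_texts"):
            for oid in getattr(ctx, role):
                text_claims.setdefault(oid, []).append((ctx, role))
    for oid, holders in text_claims.items():
        if len(holders) < 2:
            continue
        best = min(holders,
                   key=lambda h: distance_to_segment(text_center[oid], h[0].arrow))
        for holder in holders:
            if holder is not best:
                getattr(holder[0], holder[1]).remove(oid)


def _chain_edges(contexts: list[StepContext], molecules: dict[int, Molecule],
                 config: AssemblerConfig) -> list[tuple[int, int]]:
    edges: set[tuple[int, int]] = set()
    for i, ci in enumerate(contexts):
        for j, cj in enumerate(contexts):
            if i == j:
                continue
            if set(ci.product_fragments) & set(cj.reactant_fragments):
                edges.add((i, j))
                continue
            gap = ((ci.arrow.head.x - cj.arrow.tail.x) ** 2
                   + (ci.arrow.head.y - cj.arrow.tail.y) ** 2) ** 0.5
            if gap <= config.chain_gap_frac * ci.arrow.length:
                edges.add((i, j))
    # wrapped layouts: intermediate redrawn — link reading-order neighbors
    # whose product/reactant canonical SMILES intersect
    for i in range(len(contexts) - 1):
        ci, cj = contexts[i], contexts[i + 1]
        prod = {molecules[f].cano_smiles for f in ci.product_fragments
                if f in molecules}
        reac = {molecules[f].cano_smiles for f in cj.reactant_fragments
                if f in molecules}
        if prod & reac:
            edges.add((i, i + 1))
    return sorted(edges)


def _topological_chains(n: int, edges: list[tuple[int, int]]) -> list[list[int]]:
    """Split arrow indices into chains (weakly connected components in
    topological order); raises on cycles."""
    succ: dict[int, set[int]] = {i: set() for i in range(n)}
    pred: dict[int, set[int]] = {i: set() for i in range(n)}
    for i, j in edges:
        succ[i].add(j)
        pred[j].add(i)
    # cycle check (Kahn)
    indeg = {i: len(pred[i]) for i in range(n)}
    queue = sorted(i for i in range(n) if indeg[i] == 0)
    topo: list[int] = []
    while queue:
        i = queue.pop(0)
        topo.append(i)
        for j in sorted(succ[i]):
            indeg[j] -= 1
            if indeg[j] == 0:
                queue.append(j)
    if len(topo) != n:
        raise CyclicSchemeError("cyclic scheme: arrow chain contains a loop")
    # weakly connected components, each ordered by the global topo order
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        parent[find(i)] = find(j)
    comps: dict[int, list[int]] = {}
    for i in topo:
        comps.setdefault(find(i), []).append(i)
    return [comps[k] for k in sorted(comps, key=lambda k: min(comps[k]))]


_RGROUP_DEF = re.compile(r"^(R\d*'?|X)\s*=\s*(\S+)$")


def harvest_rgroup_definitions(g: SchemeGraph) -> tuple[dict[str, str], set[int]]:
    """Collect ``R = Me``-style definitions from text blocks.

    Returns the label→definition map and the ids of the consumed texts."""
    defs: dict[str, str] = {}
    used: set[int] = set()
    for t in g.texts:
        m = _RGROUP_DEF.match(t.value.strip())
        if m:
            defs[m.group(1)] = m.group(2)
            used.add(t.id)
    return defs, used


def attach_band_content(
    step: ReactionStep,
    band_molecules: list[Molecule],
    band_texts: list[TextBlock],
    libs: Libraries,
    table: PatternTable | None = None,
) -> ReactionStep:
    """Fold the band content into the step: drawn fragments become
    reagents, texts are routed through the text interpreter, identified
    compounds split solvent-vs-reagent, conditions merge into the step."""
    table = table or default_table()
    step.reagents.extend(band_molecules)
    residues: list[str] = []
    merged = ConditionSet()
    for t in band_texts:
        cls = classify_text_block(t, libs, table=table)
        for smi in cls.smiles:
            if classify_smiles_role(smi, libs) == "solvent":
                if smi not in step.solvents_smiles:
                    step.solvents_smiles.append(smi)
            elif smi not in step.reagents_smiles:
                step.reagents_smiles.append(smi)
        merged.merge(cls.conditions)
        if cls.kind == "unknown" and cls.conditions.is_empty():
            residues.append(cls.raw)
    if step.time is None:
        step.time = merged.time
    if step.temperature is None:
        step.temperature = merged.temperature
    if step.yield_percent is None:
        step.yield_percent = merged.yield_percent
    residues.extend(r for r in merged.residue if r != "+")
    if residues:
        step.description = "; ".join(
            ([step.description] if step.description else []) + residues)
    return step


def link_steps(
    g: SchemeGraph,
    contexts: list[StepContext],
    molecules: dict[int, Molecule],
    libs: Libraries,
    config: AssemblerConfig | None = None,
    table: PatternTable | None = None,
) -> list[ReactionStep]:
    """Order arrows into chains and emit one ReactionStep per arrow.

    A fragment serving as product of step *i* and reactant of step *i+1*
    appears in both steps.  Steps with an empty side are flagged incomplete
    rather than dropped."""
    config = config or AssemblerConfig()
    table = table or default_table()
    if not contexts:
        return []
    edges = _chain_edges(contexts, molecules, config)
    chains = _topological_chains(len(contexts), edges)
    texts_by_id = {t.id: t for t in g.texts}

    steps: list[ReactionStep] = []
    for chain in chains:
        for k, idx in enumerate(chain, start=1):
            ctx = contexts[idx]
            step = ReactionStep(
                reactants=[molecules[f] for f in ctx.reactant_fragments
                           if f in molecules],
                products=[molecules[f] for f in ctx.product_fragments
                          if f in molecules],
                status=interpret_arrow_style(ctx.arrow),
                step_index=k,
                arrow_id=ctx.arrow.id,
            )
            attach_band_content(
                step,
                [molecules[f] for f in ctx.band_fragments if f in molecules],
                [texts_by_id[t] for t in ctx.band_texts],
                libs, table)
            # product-adjacent text may carry the yield; labels were already
            # attached to molecules by the pipeline
            if step.yield_percent is None:
                from .textinterp import extract_yield
                side = [texts_by_id[t] for t in ctx.product_texts]
                step.yield_percent = extract_yield(side, table)
            step.incomplete = not step.reactants or not step.products
            if step.incomplete:
                log.warning("arrow %d yields an incomplete step", ctx.arrow.id)
            steps.append(step)
    return steps


def assemble(
    g: SchemeGraph,
    molecules: dict[int, Molecule],
    libs: Libraries,
    config: AssemblerConfig | None = None,
    table: PatternTable | None = None,
) -> tuple[list[ReactionStep], list[Molecule]]:
    """Full assembly: role contexts for every arrow, multi-claim pruning,
    chain splitting.  Returns (steps, isolated molecules) — every fragment
    either participates in a step or is reported isolated; nothing is
    silently dropped."""
    config = config or AssemblerConfig()
    mbl = g.median_bond_length()
    ordered = _reading_order(g.arrows, mbl)
    contexts = [assign_roles(g, a, config) for a in ordered]
    _resolve_multiclaims(g, contexts)
    steps = link_steps(g, contexts, molecules, libs, config, table)
    used: set[int] = set()
    for ctx in contexts:
        used.update(ctx.reactant_fragments, ctx.product_fragments,
                    ctx.band_fragments)
    isolated = [molecules[f.id] for f in g.fragments
                if f.id in molecules and f.id not in used]
    return steps, isolated
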