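import pytest

from chemscan.assembler import (
    assign_roles,
    interpret_arrow_style,
    link_steps,
)
from chemscan.cdxml_reader import parse_cdxml
from chemscan.drawing import Drawing, DrawnArrow, to_cdxml
from chemscan.errors import CyclicSchemeError
from chemscan.fixtures import (
    SchemeSpec,
    StepSpec,
    build_drawing,
    compare_to_truth,
    generate_scheme,
    random_spec,
)
from chemscan.layout import IdAlloc, make_text, mol_to_placed
from chemscan.model import ArrowShape, ArrowStyle, Point2D
from chemscan.pipeline import scan_bytes, scan_graph


class TestAssignRoles:
    @pytest.fixture()
    def scene(self):
        ids = IdAlloc()
        d = Drawing()
        # arrow from (200,150) to (290,150)
        d.arrows.append(DrawnArrow(id=ids(), tail=(200, 150), head=(290, 150)))
        placed = {}
        for name, (x, y) in {
            "left": (100, 150),       # beyond the tail → reactant
            "right": (320, 150),      # beyond the head → product
            "band": (230, 110),       # above mid-arrow → band
            "far": (200, 600),        # outside every zone
        }.items():
            p = mol_to_placed("CCO", ids, x, y)
            placed[name] = p.fragment.id
            d.fragments.append(p.fragment)
        d.texts.append(make_text(ids, "NEt3", 245, 120))
        g = parse_cdxml(to_cdxml(d))
        return g, placed

    def test_zone_assignment(self, scene):
        g, placed = scene
        ctx = assign_roles(g, g.arrows[0])
        # object ids are remapped on parse; map back via geometry
        frags = {f.id: f.bbox.center.x for f in g.fragments}
        reactant_x = [frags[i] for i in ctx.reactant_fragments]
        product_x = [frags[i] for i in ctx.product_fragments]
        band = ctx.band_fragments
        assigned = (set(ctx.reactant_fragments) | set(ctx.product_fragments)
                    | set(band))
        assert len(ctx.reactant_fragments) == 1 and reactant_x[0] < 200
        assert len(ctx.product_fragments) == 1 and product_x[0] > 290
        assert len(band) == 1
        assert len(assigned) == 3  # the far fragment is left unassigned
        assert len(ctx.band_texts) == 1


class TestArrowStyle:
    @pytest.mark.parametrize("style,status", [
        (ArrowStyle.CROSSED, "failed"),
        (ArrowStyle.DASHED, "planned"),
        (ArrowStyle.PLAIN, "success"),
    ])
    def test_mapping(self, style, status):
        arrow = ArrowShape(1, Point2D(0, 0), Point2D(90, 0), style=style)
        assert interpret_arrow_style(arrow) == status


class TestLinkSteps:
    @pytest.mark.parametrize("layout", ["horizontal-chain", "wrapped-chain",
                                        "vertical"])
    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_chain_identity(self, libs, layout, k):
        """A k-step linear scheme yields exactly k steps with
        product(i) = reactant(i+1) by canonical SMILES."""
        pool = ["CCO", "CC=O", "CC(=O)O", "CCOC(C)=O", "c1ccccc1"]
        steps = [StepSpec(reactants=[pool[i]], product=pool[i + 1])
                 for i in range(k)]
        spec = SchemeSpec(steps=steps, layout=layout, jitter=0.0)
        cdxml, _ = generate_scheme(spec)
        result = scan_bytes(cdxml.encode(), "chain", libs=libs)[0]
        assert len(result.steps) == k
        for i in range(k - 1):
            prod = {m.cano_smiles for m in result.steps[i].products}
            reac = {m.cano_smiles for m in result.steps[i + 1].reactants}
            assert prod & reac
        assert [s.step_index for s in result.steps] == list(range(1, k + 1))

    def test_two_reactants_one_product(self, libs):
        spec = SchemeSpec(steps=[StepSpec(reactants=["CCO", "CC(=O)O"],
                                          product="CCOC(C)=O")], jitter=0.0)
        cdxml, truth = generate_scheme(spec)
        result = scan_bytes(cdxml.encode(), "ab", libs=libs)[0]
        assert len(result.steps) == 1
        assert len(result.steps[0].reactants) == 2
        assert len(result.steps[0].products) == 1
        assert compare_to_truth(result.steps, truth) == []

    def test_no_arrows_molecule_only_mode(self, libs):
        ids = IdAlloc()
        d = Drawing()
        d.fragments.append(mol_to_placed("CCO", ids, 0, 0).fragment)
        d.fragments.append(mol_to_placed("c1ccccc1", ids, 200, 0).fragment)
        result = scan_graph(parse_cdxml(to_cdxml(d)), libs)
        assert result.steps == []
        assert sorted(m.cano_smiles for m in result.molecules) == \
            ["CCO", "c1ccccc1"]

    def test_cyclic_arrow_graph_rejected(self, libs):
        g = parse_cdxml(
            '<CDXML><page>'
            '<arrow id="1" Tail3D="0 0 0" Head3D="90 0 0"/>'
            '<arrow id="2" Tail3D="90 0 0" Head3D="0 0 0"/>'
            "</page></CDXML>")
        from chemscan.assembler import assign_roles

        contexts = [assign_roles(g, a) for a in g.arrows]
        with pytest.raises(CyclicSchemeError):
            link_steps(g, contexts, {}, libs)

    def test_unassigned_arrow_flagged_incomplete(self, libs):
        g = parse_cdxml('<CDXML><page>'
                        '<arrow id="1" Tail3D="0 0 0" Head3D="90 0 0"/>'
                        "</page></CDXML>")
        result = scan_graph(g, libs)
        assert len(result.steps) == 1
        assert result.steps[0].incomplete


class TestInvariance:
    @pytest.mark.parametrize("seed", [3, 17, 42])
    def test_translation_and_scaling(self, libs, seed):
        """Rigid translation and positive uniform scaling change nothing."""
        d, truth = build_drawing(random_spec(seed))
        for transform in (lambda x: x.translate(1000, 1000),
                          lambda x: x.translate(-1000, -1000),
                          lambda x: x.scale(0.5),
                          lambda x: x.scale(2.0)):
            out = scan_bytes(to_cdxml(transform(d)).encode(), "t", libs=libs)
            assert compare_to_truth(out[0].steps, truth) == []

    def test_nothing_silently_dropped(self, libs):
        """An off-scheme molecule is reported isolated, not lost."""
        d, _ = build_drawing(random_spec(5, max_steps=1, jitter=0.0))
        ids = IdAlloc(start=90000)
        d.fragments.append(mol_to_placed("C1CCCCC1", ids, 2000, 2000).fragment)
        result = scan_bytes(to_cdxml(d).encode(), "iso", libs=libs)[0]
        assert "C1CCCCC1" in [m.cano_smiles for m in result.molecules]
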