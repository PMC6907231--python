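import pytest

from chemscan.cdxml_reader import parse_cdxml, parse_coordinate
from chemscan.errors import NotCdxml
from chemscan.model import ArrowStyle, NodeKind, Point2D


class TestParseCdxml:
    def test_benzene_counts(self, ring_cdxml):
        g = parse_cdxml(ring_cdxml())
        assert len(g.fragments) == 1
        assert len(g.fragments[0].atoms) == 6
        assert len(g.fragments[0].bonds) == 6
        assert g.arrows == []
        orders = sorted(str(b.order) for b in g.fragments[0].bonds)
        assert orders == ["1", "1", "1", "2", "2", "2"]

    def test_empty_document(self):
        g = parse_cdxml('<?xml version="1.0"?><CDXML><page id="1"/></CDXML>')
        assert g.fragments == [] and g.arrows == [] and g.texts == []

    def test_text_block(self):
        g = parse_cdxml('<CDXML><page><t id="3" p="100 50">'
                        "<s>NEt3</s></t></page></CDXML>")
        assert len(g.texts) == 1
        assert g.texts[0].value == "NEt3"

    def test_styled_runs_concatenate(self):
        g = parse_cdxml('<CDXML><page><t p="0 0"><s>NEt</s><s>3</s></t>'
                        "</page></CDXML>")
        assert g.texts[0].value == "NEt3"

    def test_non_xml_error_names_offset(self):
        with pytest.raises(NotCdxml) as exc:
            parse_cdxml("this is not xml at all")
        assert "offset" in str(exc.value)

    def test_wrong_root(self):
        with pytest.raises(NotCdxml, match="not CDXML"):
            parse_cdxml("<html/>")

    def test_sibling_order_insensitive(self, ring_cdxml):
        """Permuting sibling elements yields the same graph content."""
        text = ring_cdxml()
        from lxml import etree

        root = etree.fromstring(text.encode())
        page = root.find("page")
        for child in reversed(list(page)):
            page.remove(child)
            page.append(child)
        g1 = parse_cdxml(text)
        g2 = parse_cdxml(etree.tostring(root))
        key = lambda g: sorted(
            (len(f.atoms), len(f.bonds),
             sorted(str(b.order) for b in f.bonds)) for f in g.fragments)
        assert key(g1) == key(g2)


class TestNodes:
    def test_node_without_element_attribute_is_carbon(self):
        g = parse_cdxml('<CDXML><page><fragment id="1">'
                        '<n id="2" p="0 0"/></fragment></page></CDXML>')
        atom = g.fragments[0].atoms[0]
        assert atom.element == 6 and atom.node_kind == NodeKind.ELEMENT

    def test_labelled_node_without_inner_fragment_is_abbreviation(self):
        g = parse_cdxml('<CDXML><page><fragment id="1">'
                        '<n id="2" p="0 0" NodeType="Nickname">'
                        "<t><s>OMe</s></t></n></fragment></page></CDXML>")
        atom = g.fragments[0].atoms[0]
        assert atom.node_kind == NodeKind.ABBREVIATION
        assert atom.label == "OMe"

    @pytest.mark.parametrize("label", ["R", "R1", "R'", "X"])
    def test_r_group_pattern(self, label):
        g = parse_cdxml(f'<CDXML><page><fragment id="1"><n id="2" p="0 0">'
                        f"<t><s>{label}</s></t></n></fragment></page></CDXML>")
        assert g.fragments[0].atoms[0].node_kind == NodeKind.R_GROUP

    def test_bare_heteroatom_label_stays_element(self):
        g = parse_cdxml('<CDXML><page><fragment id="1">'
                        '<n id="2" p="0 0" Element="7"><t><s>N</s></t></n>'
                        "</fragment></page></CDXML>")
        atom = g.fragments[0].atoms[0]
        assert atom.node_kind == NodeKind.ELEMENT and atom.element == 7

    def test_charge_and_isotope(self):
        g = parse_cdxml('<CDXML><page><fragment id="1">'
                        '<n id="2" p="0 0" Element="8" Charge="-1" '
                        'Isotope="18"/></fragment></page></CDXML>')
        atom = g.fragments[0].atoms[0]
        assert atom.charge == -1 and atom.isotope == 18

    def test_nested_inner_fragment_is_authoritative(self, libs):
        """An abbreviation node carrying its own expansion uses the drawn
        expansion (here OH) and skips library lookup."""
        text = ('<CDXML><page><fragment id="1">'
                '<n id="2" p="0 0" Element="6"/>'
                '<n id="3" p="30 0" NodeType="Nickname">'
                "<t><s>Qxx</s></t>"  # not in any library
                '<fragment id="4">'
                '<n id="5" p="30 0" Element="8"/>'
                '<n id="6" p="40 0" NodeType="ExternalConnectionPoint"/>'
                '<b id="7" B="6" E="5"/>'
                "</fragment></n>"
                '<b id="8" B="2" E="3"/>'
                "</fragment></page></CDXML>")
        g = parse_cdxml(text)
        from chemscan.builder import build_molecule

        m = build_molecule(g.fragments[0], libs)
        assert m.cano_smiles == "CO"


class TestArrows:
    def test_modern_arrow_with_styles(self):
        text = ('<CDXML><page>'
                '<arrow id="1" Tail3D="0 0 0" Head3D="90 0 0"/>'
                '<arrow id="2" Tail3D="0 50 0" Head3D="90 50 0" '
                'LineType="Dashed"/>'
                '<arrow id="3" Tail3D="0 99 0" Head3D="90 99 0" '
                'NoGo="Cross"/></page></CDXML>')
        g = parse_cdxml(text)
        assert [a.style for a in g.arrows] == [
            ArrowStyle.PLAIN, ArrowStyle.DASHED, ArrowStyle.CROSSED]
        assert g.arrows[0].tail == Point2D(0, 0)
        assert g.arrows[0].head == Point2D(90, 0)

    def test_legacy_graphic_arrow_head_first(self):
        text = ('<CDXML><page><graphic id="1" GraphicType="Line" '
                'ArrowType="FullHead" BoundingBox="90 10 0 10"/>'
                "</page></CDXML>")
        g = parse_cdxml(text)
        assert len(g.arrows) == 1
        assert g.arrows[0].head == Point2D(90, 10)
        assert g.arrows[0].tail == Point2D(0, 10)

    def test_overlapping_nogo_symbol_crosses_arrow(self):
        text = ('<CDXML><page>'
                '<arrow id="1" Tail3D="0 0 0" Head3D="90 0 0"/>'
                '<graphic id="2" GraphicType="Symbol" SymbolType="NoGo" '
                'BoundingBox="40 -5 50 5"/></page></CDXML>')
        g = parse_cdxml(text)
        assert g.arrows[0].style == ArrowStyle.CROSSED


class TestParseCoordinate:
    @pytest.mark.parametrize("attr,expected", [
        ("0 0", Point2D(0, 0)),
        ("12.5 -3", Point2D(12.5, -3)),
        ("1e2 4", Point2D(100, 4)),
    ])
    def test_valid(self, attr, expected):
        assert parse_coordinate(attr) == expected

    def test_wrong_token_count(self):
        with pytest.raises(NotCdxml):
            parse_coordinate("1 2 3")
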