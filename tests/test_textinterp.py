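import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemscan.library import canonicalize
from chemscan.model import Point2D, Rect, TextBlock
from chemscan.textinterp import (
    Quantity,
    classify_text_block,
    extract_yield,
    parse_conditions,
)


def text_block(value: str, cx: float = 0.0, cy: float = 0.0) -> TextBlock:
    return TextBlock(id=1, value=value,
                     bbox=Rect(Point2D(cx - 10, cy - 5), Point2D(cx + 10, cy + 5)))


class TestParseConditions:
    def test_temperature_and_time(self):
        c = parse_conditions("80 °C, 12 h")
        assert c.temperature == Quantity(80.0, "°C")
        assert c.time == Quantity(12.0, "h")
        assert c.residue == []

    def test_qualitative_tokens(self):
        c = parse_conditions("rt, overnight")
        assert c.temperature == "rt" and c.time == "overnight"

    def test_empty_string(self):
        c = parse_conditions("")
        assert c.is_empty()

    @pytest.mark.parametrize("text,expected", [
        ("95%", 95.0),
        ("yield: 73 %", 73.0),
        ("85.5%", 85.5),
    ])
    def test_yield_tokens(self, text, expected):
        assert parse_conditions(text).yield_percent == expected

    def test_decimal_comma(self):
        c = parse_conditions("1,5 h")
        assert c.time == Quantity(1.5, "h")

    def test_unit_synonyms_canonicalized(self):
        assert parse_conditions("3 hrs").time == Quantity(3.0, "h")
        assert parse_conditions("2 days").time == Quantity(2.0, "d")

    def test_unmatched_tokens_become_residue(self):
        c = parse_conditions("80 °C, with vigorous stirring")
        assert c.residue == ["with vigorous stirring"]

    times = st.one_of(
        st.just("overnight"),
        st.tuples(st.integers(1, 48), st.sampled_from(["min", "h", "d"])))
    temps = st.one_of(
        st.sampled_from(["rt", "reflux"]),
        st.tuples(st.integers(-78, 200), st.just("°C")))

    @settings(max_examples=60, derandomize=True)
    @given(time=times, temp=temps, yld=st.none() | st.integers(1, 99))
    def test_render_parse_identity(self, time, temp, yld):
        """Rendering a condition set to text and parsing it back is the
        identity on the fixture grammar."""
        tokens = []
        want_temp = temp if isinstance(temp, str) else \
            Quantity(float(temp[0]), temp[1])
        tokens.append(temp if isinstance(temp, str) else
                      f"{temp[0]} {temp[1]}")
        want_time = time if isinstance(time, str) else \
            Quantity(float(time[0]), time[1])
        tokens.append(time if isinstance(time, str) else
                      f"{time[0]} {time[1]}")
        if yld is not None:
            tokens.append(f"{yld}%")
        c = parse_conditions(", ".join(tokens))
        assert c.temperature == want_temp
        assert c.time == want_time
        assert c.yield_percent == (None if yld is None else float(yld))
        assert c.residue == []


class TestClassifyTextBlock:
    def test_known_name_is_compound(self, libs):
        cls = classify_text_block(text_block("DMF"), libs)
        assert cls.kind == "compound"
        assert cls.smiles == [canonicalize("CN(C)C=O")]

    def test_mixed_compound_and_condition(self, libs):
        cls = classify_text_block(text_block("NaH, 0 °C"), libs)
        assert cls.kind == "compound"
        assert cls.smiles == [canonicalize("[H-].[Na+]")]
        assert cls.conditions.temperature == Quantity(0.0, "°C")

    def test_raw_smiles_token_accepted(self, libs):
        cls = classify_text_block(text_block("CCOC(C)=O"), libs)
        assert cls.smiles == [canonicalize("CCOC(C)=O")]

    def test_label_below_fragment(self, libs, ring_cdxml):
        from chemscan.cdxml_reader import parse_cdxml

        g = parse_cdxml(ring_cdxml())
        frag = g.fragments[0]
        below = frag.bbox.max.y + 20
        cls = classify_text_block(
            text_block("13a", cx=frag.bbox.center.x, cy=below), libs,
            fragments=[frag], median_bond_length=30.0)
        assert cls.kind == "label" and cls.label == "13a"

    def test_unknown_preserves_raw(self, libs):
        cls = classify_text_block(text_block("via Mitsunobu"), libs)
        assert cls.kind == "unknown"
        assert cls.raw == "via Mitsunobu"

    def test_no_token_lost(self, libs):
        """Compounds + conditions + residue jointly account for the input."""
        cls = classify_text_block(
            text_block("NEt3, THF, 80 °C, 2 h, dropwise"), libs)
        assert len(cls.smiles) == 2
        assert cls.conditions.temperature == Quantity(80.0, "°C")
        assert cls.conditions.time == Quantity(2.0, "h")
        assert cls.conditions.residue == ["dropwise"]


class TestExtractYield:
    def test_bare_percentage(self):
        assert extract_yield([text_block("95%")]) == 95.0

    def test_prefixed(self):
        assert extract_yield([text_block("yield: 73 %")]) == 73.0

    def test_absent(self):
        assert extract_yield([text_block("no luck")]) is None

    def test_first_wins_on_duplicates(self):
        assert extract_yield([text_block("40%"), text_block("90%")]) == 40.0
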