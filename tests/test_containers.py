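import pytest

from chemscan.containers import (
    ElnReactionRecord,
    extract_from_doc,
    extract_from_docx,
    extract_from_eln_xml,
    reconcile,
    scan_for_cdx_signatures,
)
from chemscan.cdx_format import MAGIC
from chemscan.errors import NotDoc, NotDocx
from chemscan.fixtures import (
    SchemeSpec,
    StepSpec,
    generate_scheme,
    generate_scheme_cdx,
    random_spec,
    wrap_in_container,
)
from chemscan.pipeline import scan_bytes


@pytest.fixture(scope="module")
def cdx_payload():
    return generate_scheme_cdx(random_spec(11, jitter=0.0))[0]


class TestDocx:
    def test_round_trip_single_payload(self, cdx_payload):
        docx = wrap_in_container(cdx_payload, "docx")
        got = extract_from_docx(docx)
        assert len(got) == 1
        assert got[0].data == cdx_payload
        assert got[0].dialect == "cdx"

    def test_two_payloads_in_document_order(self, cdx_payload):
        other = generate_scheme_cdx(random_spec(12, jitter=0.0))[0]
        docx = wrap_in_container([cdx_payload, other], "docx")
        got = extract_from_docx(docx)
        assert [p.data for p in got] == [cdx_payload, other]

    def test_empty_docx_yields_empty_list(self):
        import io
        import zipfile

        buf = io.BytesIO()
        with zipfile.ZipFile(buf, "w") as zf:
            zf.writestr("[Content_Types].xml", "<Types/>")
        assert extract_from_docx(buf.getvalue()) == []

    def test_not_a_zip(self):
        with pytest.raises(NotDocx):
            extract_from_docx(b"definitely not a zip")


class TestDoc:
    def test_round_trip(self, cdx_payload):
        doc = wrap_in_container(cdx_payload, "doc")
        got = extract_from_doc(doc)
        assert len(got) == 1 and got[0].data == cdx_payload
        assert "ObjectPool" in got[0].origin

    def test_ole_without_object_pool(self):
        from chemscan import cfb

        empty = cfb.build({"WordDocument": b"\x00" * 64})
        assert extract_from_doc(empty) == []

    def test_signature_scan_fallback(self, cdx_payload):
        """A payload buried in a non-OLE region is recovered by magic scan
        when the file is not a walkable compound file."""
        from chemscan import cfb

        # valid OLE shell with the CDX hidden inside an opaque stream tail
        blob = b"\x00" * 100 + cdx_payload + b"\x00" * 40
        doc = cfb.build({"WordDocument": blob})
        got = extract_from_doc(doc)
        assert len(got) == 1
        assert got[0].data == cdx_payload
        assert "signature-scan" in got[0].origin

    def test_not_ole(self):
        with pytest.raises(NotDoc):
            extract_from_doc(b"plain text")


class TestSignatureScan:
    def test_no_magic(self):
        assert scan_for_cdx_signatures(b"abcdef") == []

    def test_magic_at_zero(self):
        assert scan_for_cdx_signatures(MAGIC + b"xx") == [0]

    def test_two_occurrences_ascending(self):
        data = b"--" + MAGIC + b"ooo" + MAGIC
        assert scan_for_cdx_signatures(data) == [2, 13]


class TestElnXml:
    def test_scheme_and_table(self):
        cdxml, _ = generate_scheme(random_spec(13, max_steps=1, jitter=0.0))
        records = [ElnReactionRecord("reactant", "CCO", amounts="1 mmol"),
                   ElnReactionRecord("solvent", "THF"),
                   ElnReactionRecord("product", "CC=O")]
        eln = wrap_in_container(cdxml.encode(), "eln_xml", records=records)
        payloads, got = extract_from_eln_xml(eln)
        assert len(payloads) == 1 and payloads[0].dialect == "cdxml"
        assert len(got) == 3
        assert got[1].role == "solvent" and got[1].identifier == "THF"
        assert got[0].amounts == "1 mmol"

    def test_unrelated_xml(self):
        payloads, records = extract_from_eln_xml("<foo><bar/></foo>")
        assert payloads == [] and records == []


@pytest.fixture(scope="module")
def one_step(libs):
    spec = SchemeSpec(steps=[StepSpec(
        reactants=["CCO"], product="CC=O", solvent="THF")], jitter=0.0)
    cdxml, _ = generate_scheme(spec)
    return scan_bytes(cdxml.encode(), "eln", libs=libs)[0].steps


class TestReconcile:

    def test_identical_sets_no_discrepancies(self, one_step, libs):
        records = [ElnReactionRecord("reactant", "CCO"),
                   ElnReactionRecord("solvent", "THF"),
                   ElnReactionRecord("product", "CC=O")]
        assert reconcile(one_step, records, libs) == []

    def test_table_compound_missing_from_scheme(self, one_step, libs):
        records = [ElnReactionRecord("reactant", "CCO"),
                   ElnReactionRecord("solvent", "THF"),
                   ElnReactionRecord("product", "CC=O"),
                   ElnReactionRecord("solvent", "EtOH")]
        # EtOH resolves to ethanol which IS the reactant here; use DMSO
        records[-1] = ElnReactionRecord("solvent", "DMSO")
        out = reconcile(one_step, records, libs)
        assert [d.kind for d in out] == ["missing-in-scheme"]
        assert out[0].identifier == "DMSO"

    def test_scheme_product_missing_from_table(self, one_step, libs):
        records = [ElnReactionRecord("reactant", "CCO"),
                   ElnReactionRecord("solvent", "THF")]
        out = reconcile(one_step, records, libs)
        assert [d.kind for d in out] == ["missing-in-table"]
        assert out[0].smiles == "CC=O"

    def test_unresolvable_identifier_reported_not_fatal(self, one_step, libs):
        records = [ElnReactionRecord("reactant", "CCO"),
                   ElnReactionRecord("solvent", "THF"),
                   ElnReactionRecord("product", "CC=O"),
                   ElnReactionRecord("reagent", "florblitzium salt")]
        out = reconcile(one_step, records, libs)
        assert [d.kind for d in out] == ["unresolved-identifier"]
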