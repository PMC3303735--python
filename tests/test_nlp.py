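"""Report sectionizing, coded-field extraction and XML round-trips."""

import datetime as dt

import pytest
from hypothesis import given, settings, strategies as st

from oncostar import nlp
from oncostar.nlp import (
    ExtractionResult,
    FieldRangeError,
    MissingSectionError,
    TnmStage,
    ValidationError,
    default_config,
    extract_biomarkers,
    extract_report,
    extract_snomed,
    extract_tnm,
    read_xml,
    sectionize,
    write_xml,
)

CFG = default_config()

REPORT = """PATHOLOGY REPORT
Report ID: R0000001
Date: 2005-03-14
Type: Histological examination
Specimen number: 2005/00123

ANAMNESIS
Known nodule of the left breast. An outside review reported Ki-67 70% last year.

MACROSCOPIC DESCRIPTION
Nodular fragment measuring 18 mm, firm, whitish cut surface.

DIAGNOSIS
Infiltrating duct carcinoma (M-85003).
Comedocarcinoma (M-85013).
Stage: pT2 N1 M0
Grade: G2
ER: 80%
PR: 10%
Ki-67: 10%
c-erb-B2 (DAKO HercepTest): 2+
"""


class TestSectionize:
    def test_three_sections_split_correctly(self):
        doc = sectionize(REPORT, CFG)
        assert set(doc.sections) == {"preamble", "anamnesis", "macroscopic",
                                     "diagnosis"}
        assert "Infiltrating duct carcinoma" in doc.sections["diagnosis"]
        assert "outside review" in doc.sections["anamnesis"]
        assert "outside review" not in doc.sections["diagnosis"]
        assert doc.report_id == "R0000001"
        assert doc.report_date == dt.date(2005, 3, 14)

    def test_sections_are_verbatim_slices(self):
        doc = sectionize(REPORT, CFG)
        for text in doc.sections.values():
            assert text in doc.raw_text

    def test_only_diagnosis_header(self):
        doc = sectionize("DIAGNOSIS\nCarcinoma (M-80103).\n", CFG)
        assert "Carcinoma" in doc.sections["diagnosis"]

    def test_no_headers_is_missing_section(self):
        with pytest.raises(MissingSectionError):
            sectionize("Report ID: R1\njust prose\n", CFG)

    def test_italian_header_alias(self):
        doc = sectionize("DIAGNOSI\nCarcinoma (M-80103).\n", CFG)
        assert "Carcinoma" in doc.sections["diagnosis"]


class TestSnomed:
    def test_two_codes_in_order(self):
        pairs, unknown = extract_snomed(
            "Comedocarcinoma (M-85013). Also M-85003.", CFG.snomed_lexicon
        )
        assert [c for c, _ in pairs] == ["M-85013", "M-85003"]
        assert pairs[1][1] == "Infiltrating duct carcinoma"
        assert unknown == []

    def test_empty_text(self):
        assert extract_snomed("", CFG.snomed_lexicon) == ([], [])

    def test_unknown_code_reported_separately(self):
        pairs, unknown = extract_snomed("Lesion M-99999.", CFG.snomed_lexicon)
        assert pairs == [] and unknown == ["M-99999"]

    def test_duplicates_deduplicated(self):
        pairs, _ = extract_snomed("M-85003 and again M-85003",
                                  CFG.snomed_lexicon)
        assert len(pairs) == 1


class TestTnm:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("pT2 N1 M0", TnmStage("2", "1", "0", "p")),
            ("Tis N0 M0", TnmStage("is", "0", "0")),
            ("ypT1c N2a MX", TnmStage("1c", "2a", "X", "yp")),
            ("stage cT4b, N3, M1", TnmStage("4b", "3", "1", "c")),
            ("T1 N1a M0", TnmStage("1", "1a", "0")),
        ],
    )
    def test_grammar(self, text, expected):
        assert extract_tnm(text) == expected

    def test_absent(self):
        assert extract_tnm("no staging information here") is None

    def test_conflicting_mentions_first_wins(self, caplog):
        with caplog.at_level("WARNING"):
            stage = extract_tnm("pT2 N1 M0 ... later revised to pT3 N2 M1")
        assert stage.t == "2"
        assert "conflicting" in caplog.text

    def test_serialization_round_trips(self):
        for stage in (TnmStage("2", "1", "0", "p"), TnmStage("is", "0", "X"),
                      TnmStage("4d", "2a", "1", "yp")):
            assert TnmStage.parse(stage.serialize()) == stage

    def test_invalid_component_rejected(self):
        with pytest.raises(ValidationError):
            TnmStage("5", "0", "0")


class TestBiomarkers:
    @pytest.mark.parametrize(
        "text, field, value",
        [
            ("Ki-67: 25%", "ki67", 25.0),
            ("Ki67 8%", "ki67", 8.0),
            ("c-erbB2 (DAKO): 3+", "c_erb_b2", 3),
            ("HER-2 score: 0", "c_erb_b2", 0),
            ("ER: 90%", "estrogens_receptors", 90.0),
            ("Estrogens receptors: 0%", "estrogens_receptors", 0.0),
            ("PR: 15%", "progesterone_receptors", 15.0),
            ("Grade: G2", "grade", 2),
            ("grade 3", "grade", 3),
            ("ER: positive", "er_status", "positive"),
            ("PR: negative", "pr_status", "negative"),
        ],
    )
    def test_single_field(self, text, field, value):
        assert extract_biomarkers(text, CFG).get(field) == value

    def test_percent_out_of_range(self):
        with pytest.raises(FieldRangeError, match="estrogens_receptors"):
            extract_biomarkers("ER 120%", CFG)

    def test_percent_beats_qualitative(self):
        out = extract_biomarkers("ER: 40% (positive)", CFG)
        assert out["estrogens_receptors"] == 40.0
        assert "er_status" not in out


class TestExtractReport:
    def test_full_template(self):
        res = extract_report(REPORT, CFG)
        assert res.name == "R0000001"
        assert res.date == dt.date(2005, 3, 14)
        assert res.type == "histological"
        assert res.number == "2005/00123"
        assert res.snomed == [("M-85003", "Infiltrating duct carcinoma"),
                              ("M-85013", "Comedocarcinoma")]
        assert res.state == TnmStage("2", "1", "0", "p")
        assert (res.grade, res.estrogens_receptors,
                res.progesterone_receptors, res.ki67, res.c_erb_b2) \
            == (2, 80.0, 10.0, 10.0, 2)

    def test_anamnesis_decoy_never_wins(self):
        """Ki-67 70% in the anamnesis must lose to 10% in the diagnosis."""
        res = extract_report(REPORT, CFG)
        assert res.ki67 == 10.0

    def test_cytological_without_tnm(self):
        text = ("Report ID: R2\nDate: 2006-01-02\n"
                "Type: Cytological examination\n\nDIAGNOSIS\n"
                "Carcinoma not otherwise specified (M-80103).\n")
        res = extract_report(text, CFG)
        assert res.type == "cytological"
        assert res.state is None

    def test_determinism(self):
        assert extract_report(REPORT, CFG) == extract_report(REPORT, CFG)


# --------------------------------------------------------------------------
# XML round-trip (randomized over valid records)
# --------------------------------------------------------------------------

_LEX = sorted(CFG.snomed_lexicon.items())

percents = st.one_of(
    st.integers(0, 100).map(float),
    st.integers(0, 1000).map(lambda n: n / 10.0),
)


@st.composite
def extraction_results(draw):
    res = ExtractionResult(
        name=draw(st.from_regex(r"R[0-9]{4,7}", fullmatch=True)),
        date=draw(st.one_of(st.none(), st.dates(dt.date(1990, 1, 1),
                                                dt.date(2030, 1, 1)))),
        type=draw(st.sampled_from(["histological", "cytological"])),
        number=draw(st.one_of(st.none(),
                              st.from_regex(r"[0-9]{4}/[0-9]{1,5}",
                                            fullmatch=True))),
        snomed=draw(st.lists(st.sampled_from(_LEX), unique=True, max_size=4)),
    )
    if draw(st.booleans()):
        res.state = TnmStage(
            draw(st.sampled_from(nlp.T_VALUES)),
            draw(st.sampled_from(nlp.N_VALUES)),
            draw(st.sampled_from(nlp.M_VALUES)),
            draw(st.sampled_from((None, "c", "p", "yp"))),
        )
    res.grade = draw(st.one_of(st.none(), st.sampled_from([1, 2, 3])))
    res.ki67 = draw(st.one_of(st.none(), percents))
    res.c_erb_b2 = draw(st.one_of(st.none(), st.sampled_from([0, 1, 2, 3])))
    if draw(st.booleans()):
        res.estrogens_receptors = draw(percents)
    elif draw(st.booleans()):
        res.er_status = draw(st.sampled_from(["positive", "negative"]))
    if draw(st.booleans()):
        res.progesterone_receptors = draw(percents)
    return res


class TestXmlRoundTrip:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(extraction_results())
    def test_read_write_identity(self, result):
        assert read_xml(write_xml(result)) == result

    def test_minimal_document_omits_optionals(self):
        res = ExtractionResult(name="R1", date=dt.date(2010, 5, 1))
        xml = write_xml(res)
        assert b"<Ki67>" not in xml and b"<snomed>" not in xml
        assert read_xml(xml) == res

    def test_snomed_pairs_serialized_as_code_name_children(self):
        res = ExtractionResult(name="R1", snomed=_LEX[:2])
        xml = write_xml(res)
        from lxml import etree

        sn = etree.fromstring(xml).find("snomed")
        assert [el.tag for el in sn] == ["code", "name", "code", "name"]
        assert read_xml(xml).snomed == _LEX[:2]

    def test_missing_name_rejected(self):
        bad = (b"<document><date>2010-01-01</date>"
               b"<type>histological</type></document>")
        with pytest.raises(ValidationError):
            read_xml(bad)

    def test_schema_rejects_bad_score(self):
        bad = (b"<document><name>R1</name><date></date>"
               b"<type>histological</type><c-erb_B2>7</c-erb_B2></document>")
        with pytest.raises(ValidationError, match="c-erb_B2"):
            read_xml(bad)

    def test_historic_receptor_spelling_tolerated_on_read(self):
        doc = (b"<document><name>R1</name><date></date>"
               b"<type>histological</type>"
               b"<progesterone_recoptors>12</progesterone_recoptors>"
               b"</document>")
        assert read_xml(doc).progesterone_receptors == 12.0

    def test_malformed_xml(self):
        with pytest.raises(ValidationError, match="malformed"):
            read_xml(b"<document><name>")


def test_section_restriction_is_total(pipeline):
    """Replacing everything outside the diagnosis section never changes any
    extracted field."""
    import re

    for rid, text in sorted(pipeline.cohort.report_texts.items())[:25]:
        res1 = extract_report(text, CFG)
        mutated = re.sub(r"(?s)(ANAMNESIS\n).*?(\n\nMACROSCOPIC)",
                         r"\1Ki-67 99% ER 1% pT4 N3 M1 G1\2", text)
        res2 = extract_report(mutated, CFG)
        assert res1 == res2
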