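"""Pathology-report information extraction.

Reports produced by a structured data-entry process have a predictable
shape: a short preamble (report id, date, specimen number), an anamnesis,
a macroscopic description, and a coded diagnosis section.  Extraction is a
two-stage pattern pipeline:

1. the *sectionizer* splits the report into labelled sections, and
2. field extractors run **only on the diagnosis section** — morphology
   codes, TNM stage, tumor grade, hormone receptors (ER/PR), Ki-67 and
   HER-2 — so descriptive prose and patient history never contaminate the
   coded output.

The result is serialized as a small XML document (one per report) and
validated against the packaged schema.  All patterns live in an
:class:`ExtractionConfig` so header wording (including Italian aliases)
and field syntax can be adapted without code changes.
"""

from __future__ import annotations

import datetime as _dt
import logging
import re
from dataclasses import dataclass, field, fields as _dc_fields
from importlib import resources
from pathlib import Path
from typing import Mapping

from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "ReportDocument",
    "ExtractionConfig",
    "ExtractionResult",
    "TnmStage",
    "MissingSectionError",
    "FieldRangeError",
    "ValidationError",
    "default_config",
    "load_lexicon",
    "sectionize",
    "extract_snomed",
    "extract_tnm",
    "extract_biomarkers",
    "extract_report",
    "write_xml",
    "read_xml",
    "extract_directory",
    "per_field_accuracy",
]

T_VALUES = ("X", "0", "is", "1", "1a", "1b", "1c", "2", "3", "4", "4a", "4b", "4c", "4d")
N_VALUES = ("X", "0", "1", "1a", "2", "2a", "3")
M_VALUES = ("X", "0", "1")
TNM_PREFIXES = ("c", "p", "yp")

SNOMED_CODE_PATTERN = r"\b([A-Z]-\d{5})\b"


class MissingSectionError(ValueError):
    """No coded-diagnosis section header was found in the report."""

    def __init__(self, report_id: str | None, message: str):
        super().__init__(message)
        self.report_id = report_id


class FieldRangeError(ValueError):
    """An extracted value falls outside its allowed range."""

    def __init__(self, field_name: str, value, message: str | None = None):
        super().__init__(message or f"{field_name}: value {value!r} out of range")
        self.field_name = field_name
        self.value = value


class ValidationError(ValueError):
    """A record or document violates the output schema; lists offenders."""

    def __init__(self, problems: list[str]):
        super().__init__("; ".join(problems))
        self.problems = problems


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class TnmStage:
    """Tumor / node / metastasis staging from closed vocabularies,
    with an optional clinical/pathological/post-therapy prefix."""

    t: str
    n: str
    m: str
    prefix: str | None = None

    def __post_init__(self):
        problems = []
        if self.t not in T_VALUES:
            problems.append(f"t={self.t!r}")
        if self.n not in N_VALUES:
            problems.append(f"n={self.n!r}")
        if self.m not in M_VALUES:
            problems.append(f"m={self.m!r}")
        if self.prefix is not None and self.prefix not in TNM_PREFIXES:
            problems.append(f"prefix={self.prefix!r}")
        if problems:
            raise ValidationError([f"invalid TNM component(s): {', '.join(problems)}"])

    def serialize(self) -> str:
        return f"{self.prefix or ''}T{self.t} N{self.n} M{self.m}"

    @classmethod
    def parse(cls, text: str) -> "TnmStage":
        stage = extract_tnm(text)
        if stage is None:
            raise ValidationError([f"not a TNM string: {text!r}"])
        return stage


@dataclass
class ReportDocument:
    report_id: str | None
    report_date: _dt.date | None
    raw_text: str
    sections: dict[str, str]


@dataclass
class ExtractionConfig:
    """Patterns driving the pipeline; every field has at least one pattern
    and the code lexicon is non-empty (checked on construction)."""

    section_header_patterns: dict[str, str]
    field_patterns: dict[str, str]
    snomed_lexicon: dict[str, str]
    snomed_code_pattern: str = SNOMED_CODE_PATTERN
    report_id_pattern: str = r"(?im)^\s*Report\s*ID\s*[:=]\s*(\S+)"
    report_date_pattern: str = r"(?im)^\s*(?:Report\s*)?Date\s*[:=]\s*(\S+)"
    dayfirst: bool = False

    REQUIRED_FIELDS = (
        "estrogens_receptors", "progesterone_receptors", "ki67",
        "c_erb_b2", "grade", "type", "number",
        "er_status", "pr_status",
    )

    def __post_init__(self):
        if not self.snomed_lexicon:
            raise ValueError("SNOMED lexicon must be non-empty")
        missing = [f for f in self.REQUIRED_FIELDS if f not in self.field_patterns]
        if missing:
            raise ValueError(f"field_patterns missing entries for: {missing}")
        if "diagnosis" not in self.section_header_patterns:
            raise ValueError("section_header_patterns must define 'diagnosis'")


@dataclass
class ExtractionResult:
    """Structured content of one report, mirroring the output XML.

    Percent fields live in [0, 100]; the HER-2 score is the usual
    immunohistochemistry 0/1+/2+/3+ scale.  Hormone receptors reported
    qualitatively (no percent) land in the ``*_status`` fields instead.
    """

    name: str
    date: _dt.date | None = None
    type: str = "histological"
    number: str | None = None
    estrogens_receptors: float | None = None
    progesterone_receptors: float | None = None
    ki67: float | None = None
    c_erb_b2: int | None = None
    grade: int | None = None
    state: TnmStage | None = None
    snomed: list[tuple[str, str]] = field(default_factory=list)
    er_status: str | None = None
    pr_status: str | None = None
    unknown_codes: list[str] = field(default_factory=list)

    def validate(self, lexicon: Mapping[str, str] | None = None) -> None:
        problems: list[str] = []
        for fname in ("estrogens_receptors", "progesterone_receptors", "ki67"):
            val = getattr(self, fname)
            if val is not None and not (0 <= val <= 100):
                problems.append(f"{fname} out of [0,100]: {val}")
        if self.c_erb_b2 is not None and self.c_erb_b2 not in (0, 1, 2, 3):
            problems.append(f"c_erb_b2 not in {{0,1,2,3}}: {self.c_erb_b2}")
        if self.grade is not None and self.grade not in (1, 2, 3):
            problems.append(f"grade not in {{1,2,3}}: {self.grade}")
        if self.type not in ("histological", "cytological"):
            problems.append(f"type not histological/cytological: {self.type!r}")
        for status, percent, fname in (
            (self.er_status, self.estrogens_receptors, "er_status"),
            (self.pr_status, self.progesterone_receptors, "pr_status"),
        ):
            if status is not None and status not in ("positive", "negative"):
                problems.append(f"{fname} not positive/negative: {status!r}")
            if status is not None and percent is not None:
                problems.append(f"{fname} set alongside a percent value")
        if lexicon is not None:
            bad = [c for c, _ in self.snomed if c not in lexicon]
            if bad:
                problems.append(f"snomed codes not in lexicon: {bad}")
        if problems:
            raise ValidationError(problems)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

# Header wording varies by site and language; each label maps to one
# alternation covering English and Italian forms seen in templated reports.
_DEFAULT_SECTIONS = {
    "anamnesis": r"(?i)^\s*(?:ANAMNESIS|CLINICAL\s+HISTORY|ANAMNESI)\s*:?\s*$",
    "macroscopic": r"(?i)^\s*(?:MACROSCOPIC\s+DESCRIPTION|GROSS\s+DESCRIPTION|"
                   r"DESCRIZIONE\s+MACROSCOPICA)\s*:?\s*$",
    "diagnosis": r"(?i)^\s*(?:DIAGNOSIS|PATHOLOGIC\s+DIAGNOSIS|DIAGNOSI)\s*:?\s*$",
}

_ER = r"(?:estrogens?\s+receptors?|\bER\b)"
_PR = r"(?:progesterone\s+receptors?|\bPR\b)"
_HER2 = r"(?:c[-\s]?erb[-\s_]?B[-\s]?2|HER[-\s]?2(?:/neu)?)"

_DEFAULT_FIELDS = {
    "estrogens_receptors": rf"(?i){_ER}\s*(?:\([^)]*\))?\s*[:=]?\s*(\d{{1,3}})\s*%",
    "progesterone_receptors": rf"(?i){_PR}\s*(?:\([^)]*\))?\s*[:=]?\s*(\d{{1,3}})\s*%",
    "er_status": rf"(?i){_ER}\s*(?:\([^)]*\))?\s*[:=]?\s*(positive|negative)\b",
    "pr_status": rf"(?i){_PR}\s*(?:\([^)]*\))?\s*[:=]?\s*(positive|negative)\b",
    "ki67": r"(?i)Ki[-\s]?67\s*(?:\([^)]*\))?\s*[:=]?\s*(\d{1,3})\s*%",
    "c_erb_b2": rf"(?i){_HER2}\s*(?:\([^)]*\))?\s*(?:score)?\s*[:=]?\s*([0-3])\s*\+?",
    "grade": r"(?:[Gg]rade\s*[:=]?\s*G?([1-3])\b|\bG([1-3])\b)",
    "type": r"(?i)\b(histological|cytological|istologic\w*|citologic\w*)\b",
    "number": r"(?im)^\s*Specimen\s*(?:number|no\.?|n\.)\s*[:=]\s*(\S+)",
}

_TNM_RE = re.compile(
    r"\b(?:(yp|c|p)\s*)?"
    r"T\s?(is|X|1a|1b|1c|4a|4b|4c|4d|0|1|2|3|4)"
    r"[\s,;]*N\s?(X|1a|2a|0|1|2|3)"
    r"[\s,;]*M\s?(X|0|1)\b"
)


def load_lexicon() -> dict[str, str]:
    """Code -> preferred-name lexicon derived from the packaged term tree."""
    from .ontology import load_packaged_tree

    return {n.term_id: n.preferred_name for n in load_packaged_tree().root.walk()}


def default_config(
    lexicon: Mapping[str, str] | None = None, dayfirst: bool = False
) -> ExtractionConfig:
    return ExtractionConfig(
        section_header_patterns=dict(_DEFAULT_SECTIONS),
        field_patterns=dict(_DEFAULT_FIELDS),
        snomed_lexicon=dict(lexicon) if lexicon is not None else load_lexicon(),
        dayfirst=dayfirst,
    )


# --------------------------------------------------------------------------
# pipeline stages
# --------------------------------------------------------------------------

def _parse_report_date(token: str, dayfirst: bool) -> _dt.date | None:
    token = token.strip().rstrip(".,;")
    m = re.fullmatch(r"(\d{4})-(\d{2})-(\d{2})", token)
    if m:
        return _dt.date(int(m[1]), int(m[2]), int(m[3]))
    m = re.fullmatch(r"(\d{1,2})/(\d{1,2})/(\d{4})", token)
    if m:
        a, b, y = int(m[1]), int(m[2]), int(m[3])
        day, month = (a, b) if dayfirst else (b, a)
        return _dt.date(y, month, day)
    return None


def sectionize(raw_text: str, config: ExtractionConfig) -> ReportDocument:
    """Split a report into labelled sections on configured header lines.

    Text before the first header becomes the ``preamble`` section (where
    the report id and date live).  A report without a diagnosis header is
    rejected: coded extraction would have nothing trustworthy to read.
    """
    if not raw_text:
        raise ValueError("empty report text")
    compiled = {
        label: re.compile(pat, re.MULTILINE)
        for label, pat in config.section_header_patterns.items()
    }
    # locate header lines
    headers: list[tuple[int, int, str]] = []  # (start, end-of-line, label)
    for label, rx in compiled.items():
        for m in rx.finditer(raw_text):
            headers.append((m.start(), m.end(), label))
    headers.sort()

    sections: dict[str, str] = {}
    first = headers[0][0] if headers else len(raw_text)
    if first > 0:
        sections["preamble"] = raw_text[:first]
    for i, (start, end, label) in enumerate(headers):
        nxt = headers[i + 1][0] if i + 1 < len(headers) else len(raw_text)
        if label not in sections:  # first occurrence wins
            sections[label] = raw_text[end:nxt]

    rid = None
    m = re.search(config.report_id_pattern, raw_text)
    if m:
        rid = m.group(1)
    rdate = None
    m = re.search(config.report_date_pattern, raw_text)
    if m:
        rdate = _parse_report_date(m.group(1), config.dayfirst)

    if "diagnosis" not in sections:
        raise MissingSectionError(
            rid, f"no diagnosis section header found (report id: {rid!r})"
        )
    return ReportDocument(rid, rdate, raw_text, sections)


def extract_snomed(
    text: str,
    lexicon: Mapping[str, str],
    code_pattern: str = SNOMED_CODE_PATTERN,
) -> tuple[list[tuple[str, str]], list[str]]:
    """Find morphology codes in ``text``.

    Returns ``(matched, unknown)``: codes present in the lexicon as
    ``(code, preferred_name)`` pairs in order of first appearance,
    de-duplicated; pattern-shaped codes absent from the lexicon separately.
    """
    if not lexicon:
        raise ValueError("lexicon must be non-empty")
    matched: list[tuple[str, str]] = []
    unknown: list[str] = []
    seen: set[str] = set()
    for m in re.finditer(code_pattern, text):
        code = m.group(1)
        if code in seen:
            continue
        seen.add(code)
        if code in lexicon:
            matched.append((code, lexicon[code]))
        else:
            unknown.append(code)
    return matched, unknown


def extract_tnm(text: str) -> TnmStage | None:
    """Parse the first grammar-conformant TNM mention; None if absent.

    Conflicting later mentions are logged and ignored (first wins).
    """
    matches = list(_TNM_RE.finditer(text))
    if not matches:
        return None
    first = matches[0]
    distinct = {m.groups() for m in matches}
    if len(distinct) > 1:
        logger.warning("conflicting TNM mentions %s; keeping first", sorted(distinct))
    prefix, t, n, m_ = first.groups()
    return TnmStage(t=t, n=n, m=m_, prefix=prefix)


def _first_match(rx: re.Pattern, text: str, field_name: str) -> str | None:
    hits = [next(g for g in m.groups() if g is not None) if m.groups() else m.group(0)
            for m in rx.finditer(text)]
    if not hits:
        return None
    if len(set(hits)) > 1:
        logger.warning("multiple %s mentions %s; keeping first", field_name, hits)
    return hits[0]


def extract_biomarkers(text: str, config: ExtractionConfig) -> dict:
    """Pull biomarker fields out of (diagnosis-section) text.

    Percent fields raise :class:`FieldRangeError` outside [0, 100];
    qualitative positive/negative hormone-receptor mentions are used only
    when no percent for the same receptor is present.
    """
    out: dict = {}
    rx = {f: re.compile(p) for f, p in config.field_patterns.items()}

    for fname in ("estrogens_receptors", "progesterone_receptors", "ki67"):
        tok = _first_match(rx[fname], text, fname)
        if tok is not None:
            val = float(tok)
            if not (0 <= val <= 100):
                raise FieldRangeError(fname, val)
            out[fname] = val

    tok = _first_match(rx["c_erb_b2"], text, "c_erb_b2")
    if tok is not None:
        out["c_erb_b2"] = int(tok)
    tok = _first_match(rx["grade"], text, "grade")
    if tok is not None:
        out["grade"] = int(tok)

    if "estrogens_receptors" not in out:
        tok = _first_match(rx["er_status"], text, "er_status")
        if tok is not None:
            out["er_status"] = tok.lower()
    if "progesterone_receptors" not in out:
        tok = _first_match(rx["pr_status"], text, "pr_status")
        if tok is not None:
            out["pr_status"] = tok.lower()
    return out


def extract_report(raw_text: str, config: ExtractionConfig) -> ExtractionResult:
    """Full pipeline: sectionize, then run every field extractor on the
    diagnosis section only."""
    doc = sectionize(raw_text, config)
    diag = doc.sections["diagnosis"]

    matched, unknown = extract_snomed(diag, config.snomed_lexicon,
                                      config.snomed_code_pattern)
    markers = extract_biomarkers(diag, config)
    stage = extract_tnm(diag)

    rtype = "histological"
    tok = _first_match(re.compile(config.field_patterns["type"]), raw_text, "type")
    if tok is not None:
        tok = tok.lower()
        rtype = "cytological" if tok.startswith(("cytolog", "citolog")) else "histological"

    number = None
    m = re.search(config.field_patterns["number"], raw_text)
    if m:
        number = m.group(1)

    result = ExtractionResult(
        name=doc.report_id or "",
        date=doc.report_date,
        type=rtype,
        number=number,
        state=stage,
        snomed=matched,
        unknown_codes=unknown,
        **markers,
    )
    result.validate(config.snomed_lexicon)
    return result


# --------------------------------------------------------------------------
# XML serialization
# --------------------------------------------------------------------------

_XML_ORDER = (
    "name", "date", "type", "number",
    "estrogens_receptors", "progesterone_receptors",
    "Ki67", "c-erb_B2", "grade", "state", "snomed",
)

# historic misspellings tolerated on read
_READ_ALIASES = {"progesterone_recoptors": "progesterone_receptors"}


def _schema() -> etree.XMLSchema:
    data = resources.files("oncostar.data").joinpath("extraction_result.xsd").read_bytes()
    return etree.XMLSchema(etree.fromstring(data))


def _num_text(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def write_xml(result: ExtractionResult) -> bytes:
    """Serialize one extraction result; absent optional fields are omitted.

    Hormone-receptor elements carry either the percent or the qualitative
    status word.
    """
    result.validate()
    if not result.name:
        raise ValidationError(["name (report id) is required"])
    root = etree.Element("document")
    etree.SubElement(root, "name").text = result.name
    etree.SubElement(root, "date").text = (
        result.date.isoformat() if result.date else ""
    )
    etree.SubElement(root, "type").text = result.type
    if result.number is not None:
        etree.SubElement(root, "number").text = result.number
    er = result.estrogens_receptors
    if er is not None or result.er_status is not None:
        etree.SubElement(root, "estrogens_receptors").text = (
            _num_text(er) if er is not None else result.er_status
        )
    pr = result.progesterone_receptors
    if pr is not None or result.pr_status is not None:
        etree.SubElement(root, "progesterone_receptors").text = (
            _num_text(pr) if pr is not None else result.pr_status
        )
    if result.ki67 is not None:
        etree.SubElement(root, "Ki67").text = _num_text(result.ki67)
    if result.c_erb_b2 is not None:
        etree.SubElement(root, "c-erb_B2").text = str(result.c_erb_b2)
    if result.grade is not None:
        etree.SubElement(root, "grade").text = str(result.grade)
    if result.state is not None:
        etree.SubElement(root, "state").text = result.state.serialize()
    if result.snomed:
        sn = etree.SubElement(root, "snomed")
        for code, name in result.snomed:
            etree.SubElement(sn, "code").text = code
            etree.SubElement(sn, "name").text = name
    return etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8")


def _percent_or_status(text: str) -> tuple[float | None, str | None]:
    if text in ("positive", "negative"):
        return None, text
    return float(text), None


def read_xml(document: bytes | str) -> ExtractionResult:
    """Parse and schema-validate one output document back into an
    :class:`ExtractionResult` (inverse of :func:`write_xml`)."""
    if isinstance(document, str):
        document = document.encode("utf-8")
    try:
        root = etree.fromstring(document)
    except etree.XMLSyntaxError as exc:
        raise ValidationError([f"malformed XML: {exc}"]) from exc
    for el in root.iter():
        if el.tag in _READ_ALIASES:
            el.tag = _READ_ALIASES[el.tag]
    schema = _schema()
    if not schema.validate(root):
        errs = [f"{e.path}: {e.message}" for e in schema.error_log]
        raise ValidationError(errs)

    def text(tag: str) -> str | None:
        el = root.find(tag)
        return el.text if el is not None and el.text else None

    er, er_status = _percent_or_status(text("estrogens_receptors") or "") \
        if text("estrogens_receptors") else (None, None)
    pr, pr_status = _percent_or_status(text("progesterone_receptors") or "") \
        if text("progesterone_receptors") else (None, None)

    snomed: list[tuple[str, str]] = []
    sn = root.find("snomed")
    if sn is not None:
        kids = list(sn)
        for code_el, name_el in zip(kids[0::2], kids[1::2]):
            snomed.append((code_el.text or "", name_el.text or ""))

    date_text = text("date")
    result = ExtractionResult(
        name=text("name") or "",
        date=_dt.date.fromisoformat(date_text) if date_text else None,
        type=text("type") or "histological",
        number=text("number"),
        estrogens_receptors=er,
        progesterone_receptors=pr,
        ki67=float(text("Ki67")) if text("Ki67") else None,
        c_erb_b2=int(text("c-erb_B2")) if text("c-erb_B2") else None,
        grade=int(text("grade")) if text("grade") else None,
        state=TnmStage.parse(text("state")) if text("state") else None,
        snomed=snomed,
        er_status=er_status,
        pr_status=pr_status,
    )
    result.validate()
    return result


_ACCURACY_FIELDS = (
    "date", "type", "number", "grade", "ki67", "c_erb_b2", "state",
    "estrogens_receptors", "progesterone_receptors", "er_status", "pr_status",
)


def per_field_accuracy(
    pairs: list[tuple[ExtractionResult, ExtractionResult]],
) -> tuple[int, int]:
    """Validation bookkeeping: ``(correct, total)`` over all populated
    reference fields.

    Every reference field that holds a value counts once (each morphology
    code individually); an extracted field is correct when it equals the
    reference exactly.
    """
    correct = total = 0
    for want, got in pairs:
        for fname in _ACCURACY_FIELDS:
            ref = getattr(want, fname)
            if ref is None:
                continue
            total += 1
            correct += getattr(got, fname) == ref
        for pair in want.snomed:
            total += 1
            correct += pair in got.snomed
    return correct, total


def extract_directory(
    reports_dir: str | Path, out_dir: str | Path, config: ExtractionConfig
) -> list[tuple[str, str]]:
    """Batch mode: run the pipeline over every ``*.txt`` report, write one
    XML per report plus a tab-separated manifest; returns (report, xml)
    file-name pairs."""
    reports_dir, out_dir = Path(reports_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows: list[tuple[str, str]] = []
    for path in sorted(reports_dir.glob("*.txt")):
        result = extract_report(path.read_text("utf-8"), config)
        xml_name = f"{result.name}.xml"
        (out_dir / xml_name).write_bytes(write_xml(result))
        rows.append((path.name, xml_name))
    manifest = out_dir / "manifest.tsv"
    with manifest.open("w", encoding="utf-8") as fh:
        fh.write("report_file\txml_file\n")
        for rep, xml in rows:
            fh.write(f"{rep}\t{xml}\n")
    return rows
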