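"""Seedable mock hospital ecosystem.

Generates everything the pipeline consumes — a breast-cancer cohort with
demographics, visits, templated pathology reports (rendered text *and* the
ground-truth coded record behind each), pathology-unit specimen rows with
consent flags, and survival outcomes — so every module is testable without
real data.

Defaults mirror the deployed system's published shape: the biobanked
fraction of patients is 393/6713 (the platform's reported biobank coverage)
and visit/report dates span 2001–2011.  Biomarker values follow the
distributions a breast-cancer pathology archive would show: ER/PR percents
with a point mass at 0 (receptor-negative tumors), a roughly uniform Ki-67
percent, HER-2 immunohistochemistry scores over {0..3}, TNM components from
their closed vocabularies, morphology codes from the packaged lexicon.

Donor identity fields (names, pathology-unit ids) exist **only** to
exercise the anonymization leak checks; they are written to the
pathology-unit source table and nowhere else.  All randomness flows from
one seeded ``random.Random``; the same seed reproduces the cohort byte for
byte.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .etl import (
    HisBundle,
    PROJECTS,
    PuSpecimenRecord,
    SAMPLE_TYPES,
    build_concept_dimension,
)
from .model import PatientRecord, VisitRecord
from .nlp import ExtractionResult, M_VALUES, N_VALUES, T_VALUES, TnmStage, load_lexicon
from .plugins.kaplan_meier import SurvivalRecord

__all__ = [
    "CohortParams",
    "PatientTruth",
    "ReportTruth",
    "SampleTruth",
    "GroundTruth",
    "SimulatedCohort",
    "simulate_cohort",
    "render_report",
    "write_cohort",
    "GIVEN_NAMES",
    "FAMILY_NAMES",
]

DEFAULT_BIOBANK_FRACTION = 393 / 6713
DEFAULT_WINDOW = (_dt.date(2001, 1, 1), _dt.date(2011, 12, 31))

# Donor name pools.  Chosen so that no case-normalized 4-gram of any name
# collides with text that legitimately appears in warehouse or biobank
# exports (concept names, column headers, enums); a test enforces this.
GIVEN_NAMES = (
    "Maria", "Anna", "Giulia", "Laura", "Paola", "Chiara", "Elena",
    "Silvia", "Franca", "Luisa", "Carla", "Teresa", "Rosa", "Flavia",
    "Irene", "Bianca", "Serena", "Ilaria", "Alessia", "Matilde",
    "Mauro", "Luca", "Paolo", "Andrea", "Stefano", "Duccio", "Matteo",
    "Franco", "Sergio", "Dario",
)
FAMILY_NAMES = (
    "Rossi", "Russo", "Ferrari", "Bianchi", "Romano", "Pavesi", "Ricci",
    "Marino", "Greco", "Bruno", "Gallo", "Conti", "Fontana", "Caruso",
    "Mancini", "Rizzo", "Moretti", "Barbieri", "Santoro", "Ottavi",
)

_PU_ID_ALPHABET = "JKQWXZ"  # letters absent from barcode payloads
_LOCATIONS = ("ONC1", "ONC2", "DH01", "DH02", "RAD1")
_MATERIAL_WEIGHTS = (
    ("tissue", 0.50), ("blood", 0.20), ("plasma", 0.10),
    ("serum", 0.10), ("DNA", 0.05), ("RNA", 0.05),
)


@dataclass
class CohortParams:
    n_patients: int = 100
    biobank_fraction: float = DEFAULT_BIOBANK_FRACTION
    date_window: tuple[_dt.date, _dt.date] = DEFAULT_WINDOW
    noise_level: str = "none"  # none | light | heavy
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.biobank_fraction <= 1:
            raise ValueError("biobank_fraction must be in [0, 1]")
        if self.date_window[0] >= self.date_window[1]:
            raise ValueError("date_window start must precede end")
        if self.noise_level not in ("none", "light", "heavy"):
            raise ValueError(f"unknown noise_level {self.noise_level!r}")
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")


@dataclass
class ReportTruth:
    report_id: str
    visit_id: str
    date: _dt.date
    result: ExtractionResult  # ground-truth coded record


@dataclass
class SampleTruth:
    specimen_id: str
    visit_id: str
    material_type: str
    collected_date: _dt.date
    consent_research: bool
    project: str
    sample_type: str
    description: str


@dataclass
class PatientTruth:
    patient_id: str
    pu_patient_id: str
    given_name: str
    family_name: str
    sex: str
    birth_date: _dt.date
    vital_status: str
    death_date: _dt.date | None
    visits: list[VisitRecord]
    reports: list[ReportTruth]
    samples: list[SampleTruth]
    survival: SurvivalRecord

    @property
    def biobanked(self) -> bool:
        return any(s.consent_research for s in self.samples)


@dataclass
class GroundTruth:
    patients: list[PatientTruth]
    expected_counts: dict[str, int]
    identifier_fields: list[str]

    @property
    def survival(self) -> list[SurvivalRecord]:
        return [p.survival for p in self.patients]

    def results_by_report(self) -> dict[str, ExtractionResult]:
        return {r.report_id: r.result for p in self.patients for r in p.reports}


@dataclass
class SimulatedCohort:
    params: CohortParams
    pu_records: list[PuSpecimenRecord]
    his: HisBundle
    report_texts: dict[str, str]
    truth: GroundTruth


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

def _pu_id(index: int) -> str:
    digits = []
    for _ in range(6):
        index, rem = divmod(index, len(_PU_ID_ALPHABET))
        digits.append(_PU_ID_ALPHABET[rem])
    return "PU-" + "".join(reversed(digits))


def _weighted(rng: random.Random, pairs) -> str:
    r = rng.random()
    acc = 0.0
    for value, w in pairs:
        acc += w
        if r < acc:
            return value
    return pairs[-1][0]


def _make_report_result(
    rng: random.Random, report_id: str, date: _dt.date, lexicon_codes: list[str],
    lexicon: dict[str, str],
) -> ExtractionResult:
    histological = rng.random() < 0.85
    n_codes = rng.randint(1, 3)
    codes = rng.sample(lexicon_codes, n_codes)
    res = ExtractionResult(
        name=report_id,
        date=date,
        type="histological" if histological else "cytological",
        number=f"{date.year}/{rng.randint(1, 99999):05d}",
        snomed=[(c, lexicon[c]) for c in codes],
    )
    if histological and rng.random() < 0.85:
        res.state = TnmStage(
            t=rng.choice(T_VALUES),
            n=rng.choice(N_VALUES),
            m=rng.choice(M_VALUES),
            prefix=rng.choice((None, "p", "p", "c", "yp")),
        )
    if rng.random() < 0.85:
        res.grade = rng.randint(1, 3)
    # hormone receptors: point mass at 0, occasionally qualitative only
    for pct_field, status_field in (
        ("estrogens_receptors", "er_status"),
        ("progesterone_receptors", "pr_status"),
    ):
        if rng.random() < 0.90:
            if rng.random() < 0.10:
                setattr(res, status_field, rng.choice(("positive", "negative")))
            elif rng.random() < 0.25:
                setattr(res, pct_field, 0.0)
            else:
                setattr(res, pct_field, float(rng.randint(1, 100)))
    if rng.random() < 0.90:
        res.ki67 = float(rng.randint(1, 90))
    if rng.random() < 0.85:
        res.c_erb_b2 = rng.choice((0, 1, 2, 3))
    return res


def simulate_cohort(params: CohortParams) -> SimulatedCohort:
    """Deterministically generate the full mock ecosystem for one seed."""
    rng = random.Random(params.seed)
    lexicon = load_lexicon()
    lexicon_codes = sorted(lexicon)
    start, end = params.date_window
    n_days = (end - start).days

    his = HisBundle()
    patients: list[PatientTruth] = []
    pu_records: list[PuSpecimenRecord] = []
    report_texts: dict[str, str] = {}
    report_serial = 0
    specimen_serial = 0

    for i in range(params.n_patients):
        patient_id = f"P{i:05d}"
        pu_patient_id = _pu_id(i)
        given = rng.choice(GIVEN_NAMES)
        family = rng.choice(FAMILY_NAMES)
        sex = "F" if rng.random() < 0.985 else "M"
        birth = _dt.date(rng.randint(1925, 1985), rng.randint(1, 12), rng.randint(1, 28))

        n_visits = rng.randint(1, 6)
        offsets = sorted(rng.sample(range(n_days), n_visits))
        visits = []
        for j, off in enumerate(offsets):
            d = start + _dt.timedelta(days=off)
            visits.append(
                VisitRecord(
                    f"V{i:05d}{j:02d}", patient_id, d,
                    d + _dt.timedelta(days=rng.randint(0, 2)),
                    rng.choice(_LOCATIONS),
                )
            )

        n_reports = min(len(visits), 1 + (rng.random() < 0.30))
        report_visits = sorted(
            rng.sample(visits, n_reports), key=lambda v: v.start_date
        )
        reports = []
        for v in report_visits:
            report_serial += 1
            rid = f"R{report_serial:07d}"
            res = _make_report_result(rng, rid, v.start_date, lexicon_codes, lexicon)
            reports.append(ReportTruth(rid, v.visit_id, v.start_date, res))
            his.report_index[rid] = (patient_id, v.visit_id)

        index_date = reports[0].date
        window_end = end
        death_date = None
        if rng.random() < 0.25:
            cand = index_date + _dt.timedelta(days=rng.randint(60, 2500))
            if cand <= window_end:
                death_date = cand
        vital = "deceased" if death_date else "alive"
        if death_date:
            survival = SurvivalRecord(patient_id, (death_date - index_date).days, True)
        else:
            survival = SurvivalRecord(patient_id, (window_end - index_date).days, False)

        samples: list[SampleTruth] = []
        biobanked = rng.random() < params.biobank_fraction
        if biobanked:
            for _ in range(rng.randint(1, 3)):
                specimen_serial += 1
                v = rng.choice(visits)
                samples.append(
                    SampleTruth(
                        f"SP{specimen_serial:06d}", v.visit_id,
                        _weighted(rng, _MATERIAL_WEIGHTS), v.start_date, True,
                        rng.choice(PROJECTS), rng.choice(SAMPLE_TYPES),
                        f"aliquot {len(samples) + 1}",
                    )
                )
        elif rng.random() < 0.03:
            # a specimen whose donor declined research use: never synced
            specimen_serial += 1
            v = rng.choice(visits)
            samples.append(
                SampleTruth(
                    f"SP{specimen_serial:06d}", v.visit_id,
                    _weighted(rng, _MATERIAL_WEIGHTS), v.start_date, False,
                    rng.choice(PROJECTS), rng.choice(SAMPLE_TYPES), "aliquot 1",
                )
            )

        for s in samples:
            pu_records.append(
                PuSpecimenRecord(
                    pu_patient_id=pu_patient_id,
                    specimen_id=s.specimen_id,
                    given_name=given,
                    family_name=family,
                    material_type=s.material_type,
                    collected_date=s.collected_date,
                    consent_research=s.consent_research,
                    project=s.project,
                    sample_type=s.sample_type,
                    description=s.description,
                    updated_at=_dt.datetime.combine(
                        s.collected_date + _dt.timedelta(days=rng.randint(0, 10)),
                        _dt.time(rng.randint(8, 21), rng.randint(0, 59)),
                    ),
                )
            )

        his.patients.append(PatientRecord(patient_id, sex, birth, vital, death_date))
        his.visits.extend(visits)
        his.pu_to_patient[pu_patient_id] = patient_id
        patients.append(
            PatientTruth(
                patient_id, pu_patient_id, given, family, sex, birth,
                vital, death_date, visits, reports, samples, survival,
            )
        )

    for p in patients:
        for r in p.reports:
            report_texts[r.report_id] = render_report(
                r.result, params.noise_level, rng
            )

    truth = GroundTruth(
        patients=patients,
        expected_counts=_expected_counts(patients),
        identifier_fields=sorted(
            {f for p in patients
             for f in (p.given_name, p.family_name, p.pu_patient_id)}
        ),
    )
    return SimulatedCohort(params, pu_records, his, report_texts, truth)


def _expected_counts(patients: list[PatientTruth]) -> dict[str, int]:
    """Independent tally of what the ETL should produce, computed from
    ground truth alone by the documented mapping rules."""
    n_facts = 0
    for p in patients:
        n_facts += 2  # sex + vital status
        for r in p.reports:
            res = r.result
            n_facts += len(res.snomed)
            n_facts += 3 if res.state is not None else 0
            n_facts += sum(
                x is not None
                for x in (res.grade, res.ki67, res.c_erb_b2)
            )
            n_facts += (res.estrogens_receptors is not None
                        or res.er_status is not None)
            n_facts += (res.progesterone_receptors is not None
                        or res.pr_status is not None)
        n_facts += 3 * sum(s.consent_research for s in p.samples)
    return {
        "n_patients": len(patients),
        "n_visits": sum(len(p.visits) for p in patients),
        "n_facts": n_facts,
        "n_concepts": len(build_concept_dimension()),
        "n_biobanked_patients": sum(p.biobanked for p in patients),
    }


# --------------------------------------------------------------------------
# report rendering
# --------------------------------------------------------------------------

_HEADERS = {
    "anamnesis": ("ANAMNESIS", "CLINICAL HISTORY", "ANAMNESI"),
    "macroscopic": ("MACROSCOPIC DESCRIPTION", "GROSS DESCRIPTION",
                    "DESCRIZIONE MACROSCOPICA"),
    "diagnosis": ("DIAGNOSIS", "PATHOLOGIC DIAGNOSIS", "DIAGNOSI"),
}

_ANAMNESIS_LINES = (
    "Patient referred for a palpable nodule of the left breast.",
    "Patient referred after a screening mammography finding.",
    "Known nodule of the right breast, under follow-up since last year.",
    "Patient reports a recent increase in size of a known lesion.",
)

_MACRO_LINES = (
    "Nodular fragment measuring {mm} mm, firm, whitish cut surface.",
    "Surgical specimen of {mm} mm with an ill-defined firm area.",
    "Core biopsy fragments, the largest measuring {mm} mm.",
)


def render_report(
    result: ExtractionResult, template_variant: str, rng: random.Random
) -> str:
    """Render one ground-truth record as report text.

    ``none`` renders the canonical template; ``light`` perturbs header
    wording, case and spacing (never the coded tokens); ``heavy`` may also
    drop whole field lines, so extraction can come back absent — but never
    wrong — for those fields.  Coded values appear only in the diagnosis
    section; the anamnesis may carry a decoy Ki-67 mention (an outside
    finding) that a correct extractor must ignore.
    """
    noisy = template_variant in ("light", "heavy")

    def header(label: str) -> str:
        options = _HEADERS[label]
        text = rng.choice(options) if noisy else options[0]
        if noisy and rng.random() < 0.3:
            text = text.title()
        return text

    exam = ("Histological examination" if result.type == "histological"
            else "Cytological examination")
    lines = [
        "PATHOLOGY REPORT",
        f"Report ID: {result.name}",
        f"Date: {result.date.isoformat()}",
        f"Type: {exam}",
        f"Specimen number: {result.number}",
        "",
        header("anamnesis"),
        rng.choice(_ANAMNESIS_LINES),
    ]
    if rng.random() < 0.5:
        # decoy from an outside lab: must never leak into extraction
        decoy = rng.randint(1, 99)
        if result.ki67 is not None and decoy == int(result.ki67):
            decoy = decoy % 99 + 1
        lines.append(f"An outside review reported Ki-67 {decoy}% last year.")
    lines += [
        "",
        header("macroscopic"),
        rng.choice(_MACRO_LINES).format(mm=rng.randint(4, 55)),
        "",
        header("diagnosis"),
    ]

    diag: list[str] = []
    for code, name in result.snomed:
        diag.append(f"{name} ({code}).")
    if result.state is not None:
        diag.append(f"Stage: {result.state.serialize()}")
    if result.grade is not None:
        diag.append(f"Grade: G{result.grade}")
    er_label = rng.choice(("ER", "Estrogens receptors")) if noisy else "ER"
    pr_label = rng.choice(("PR", "Progesterone receptors")) if noisy else "PR"
    if result.estrogens_receptors is not None:
        diag.append(f"{er_label}: {int(result.estrogens_receptors)}%")
    elif result.er_status is not None:
        diag.append(f"{er_label}: {result.er_status}")
    if result.progesterone_receptors is not None:
        diag.append(f"{pr_label}: {int(result.progesterone_receptors)}%")
    elif result.pr_status is not None:
        diag.append(f"{pr_label}: {result.pr_status}")
    if result.ki67 is not None:
        diag.append(f"Ki-67: {int(result.ki67)}%")
    if result.c_erb_b2 is not None:
        diag.append(f"c-erb-B2 (DAKO HercepTest): {result.c_erb_b2}+")

    if template_variant == "heavy":
        diag = [d for d in diag if not (rng.random() < 0.15 and ":" in d)]
    if noisy:
        diag = [("  " + d) if rng.random() < 0.3 else d for d in diag]

    lines += diag
    text = "\n".join(lines) + "\n"
    if noisy and rng.random() < 0.4:
        text = text.replace("\n\n", "\n\n\n", 1)
    return text


# --------------------------------------------------------------------------
# artifact writing
# --------------------------------------------------------------------------

def save_pu_records(records: list[PuSpecimenRecord], directory: str | Path) -> Path:
    import pandas as pd

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / "pu_records.tsv"
    pd.DataFrame(
        [
            {
                "pu_patient_id": r.pu_patient_id,
                "specimen_id": r.specimen_id,
                "given_name": r.given_name,
                "family_name": r.family_name,
                "material_type": r.material_type,
                "collected_date": r.collected_date.isoformat() if r.collected_date else "",
                "consent_research": str(r.consent_research).lower(),
                "project": r.project,
                "sample_type": r.sample_type,
                "description": r.description,
                "updated_at": r.updated_at.isoformat() if r.updated_at else "",
            }
            for r in records
        ],
        columns=["pu_patient_id", "specimen_id", "given_name", "family_name",
                 "material_type", "collected_date", "consent_research",
                 "project", "sample_type", "description", "updated_at"],
    ).to_csv(path, sep="\t", index=False)
    return path


def load_pu_records(directory: str | Path) -> list[PuSpecimenRecord]:
    import pandas as pd

    frame = pd.read_csv(
        Path(directory) / "pu_records.tsv", sep="\t", dtype=str, keep_default_na=False
    )
    out = []
    for r in frame.itertuples(index=False):
        out.append(
            PuSpecimenRecord(
                r.pu_patient_id, r.specimen_id, r.given_name, r.family_name,
                r.material_type,
                _dt.date.fromisoformat(r.collected_date) if r.collected_date else None,
                r.consent_research == "true", r.project, r.sample_type,
                r.description,
                _dt.datetime.fromisoformat(r.updated_at) if r.updated_at else None,
            )
        )
    return out


def write_cohort(cohort: SimulatedCohort, directory: str | Path) -> Path:
    """Write every source artifact (PU table, HIS tables, report texts,
    ground-truth tallies) plus a checksum manifest; returns the manifest
    path."""
    directory = Path(directory)
    save_pu_records(cohort.pu_records, directory / "pu")
    cohort.his.save(directory / "his")
    reports_dir = directory / "reports"
    reports_dir.mkdir(parents=True, exist_ok=True)
    for rid, text in sorted(cohort.report_texts.items()):
        (reports_dir / f"{rid}.txt").write_text(text, encoding="utf-8")
    (directory / "ground_truth.json").write_text(
        json.dumps(
            {
                "expected_counts": cohort.truth.expected_counts,
                "seed": cohort.params.seed,
                "n_patients": cohort.params.n_patients,
                "noise_level": cohort.params.noise_level,
            },
            indent=2,
        ),
        encoding="utf-8",
    )

    manifest = directory / "manifest.tsv"
    with manifest.open("w", encoding="utf-8") as fh:
        fh.write("path\tsha256\n")
        for path in sorted(directory.rglob("*")):
            if path.is_file() and path != manifest:
                digest = hashlib.sha256(path.read_bytes()).hexdigest()
                fh.write(f"{path.relative_to(directory)}\t{digest}\n")
    return manifest
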