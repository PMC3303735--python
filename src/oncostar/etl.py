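"""Synchronization and warehouse loading.

Two movements of data, modelled as explicit calls rather than scheduled
jobs:

* :func:`sync_pu_to_biobank` — the frequent pathology-unit -> biobank
  synchronization.  Each newly consented specimen receives a fresh
  anonymized barcode (linked in the segregated lookup table) and becomes a
  :class:`BiobankSample`; donor identity fields never cross this boundary.
  Non-consented specimens are skipped, malformed rows quarantined.

* :func:`load_warehouse` — the periodic merge that populates the star
  schema from the biobank store, the hospital information system and the
  report-extraction XML batch, under a fixed concept hierarchy (morphology
  codes, TNM components, biomarkers, biobank materials and meta-attributes,
  demographics).  The load is key-idempotent: re-running it with unchanged
  sources leaves every count unchanged.
"""

from __future__ import annotations

import datetime as _dt
import logging
import random
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import ontology
from .anonymize import LookupTable, new_barcode
from .model import (
    ConceptRecord,
    ObservationFact,
    PatientRecord,
    ProviderRecord,
    VisitRecord,
    Warehouse,
    parse_date,
)
from .nlp import ExtractionResult

logger = logging.getLogger(__name__)

__all__ = [
    "MATERIAL_TYPES",
    "PROJECTS",
    "SAMPLE_TYPES",
    "PROVIDERS",
    "PuSpecimenRecord",
    "BiobankSample",
    "BiobankStore",
    "SyncState",
    "SyncResult",
    "HisBundle",
    "LoadReport",
    "sync_pu_to_biobank",
    "build_concept_dimension",
    "load_warehouse",
]

MATERIAL_TYPES = ("tissue", "blood", "plasma", "serum", "DNA", "RNA", "other")
PROJECTS = ("BRC-CORE", "BRC-PILOT", "EU-COHORT")
SAMPLE_TYPES = ("diagnostic", "research", "archive")

PROVIDERS = (
    ProviderRecord("PROV-PU", "Pathology Unit", "Pathology"),
    ProviderRecord("PROV-ONC", "Oncology I", "Oncology"),
    ProviderRecord("PROV-BB", "Biobank", "Biobank"),
)

_SEX_NAMES = {"F": "Female", "M": "Male", "U": "Unknown"}
_VITAL_NAMES = {"alive": "Alive", "deceased": "Deceased", "unknown": "Unknown"}


# --------------------------------------------------------------------------
# source / store record types
# --------------------------------------------------------------------------

@dataclass
class PuSpecimenRecord:
    """One specimen row as exported by the pathology-unit database.

    Carries donor identity (names) — which must never propagate past the
    sync boundary — plus consent and meta-attributes.
    """

    pu_patient_id: str
    specimen_id: str
    given_name: str
    family_name: str
    material_type: str
    collected_date: _dt.date | None
    consent_research: bool
    project: str = ""
    sample_type: str = ""
    description: str = ""
    updated_at: _dt.datetime | None = None


@dataclass
class BiobankSample:
    """An anonymized specimen: barcode payload, material, position, consent
    and meta-attributes.  No donor identity."""

    payload: str
    material_type: str
    fridge_position: str
    consent_research: bool
    project: str = ""
    sample_type: str = ""
    creation_date: _dt.date | None = None
    description: str = ""

    @property
    def meta(self) -> dict:
        return {
            "project": self.project,
            "sample_type": self.sample_type,
            "creation_date": self.creation_date,
            "description": self.description,
        }


class BiobankStore:
    """Sample table keyed by payload, with a TSV round-trip."""

    def __init__(self):
        self.samples: dict[str, BiobankSample] = {}

    def add(self, sample: BiobankSample) -> None:
        self.samples[sample.payload] = sample

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples.values())

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        path = directory / "biobank_samples.tsv"
        rows = [
            {
                "payload": s.payload,
                "material_type": s.material_type,
                "fridge_position": s.fridge_position,
                "consent_research": str(s.consent_research).lower(),
                "project": s.project,
                "sample_type": s.sample_type,
                "creation_date": s.creation_date.isoformat() if s.creation_date else "",
                "description": s.description,
            }
            for s in sorted(self.samples.values(), key=lambda s: s.payload)
        ]
        pd.DataFrame(
            rows,
            columns=["payload", "material_type", "fridge_position",
                     "consent_research", "project", "sample_type",
                     "creation_date", "description"],
        ).to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def load(cls, directory: str | Path) -> "BiobankStore":
        frame = pd.read_csv(
            Path(directory) / "biobank_samples.tsv", sep="\t",
            dtype=str, keep_default_na=False,
        )
        store = cls()
        for r in frame.itertuples(index=False):
            store.add(
                BiobankSample(
                    r.payload, r.material_type, r.fridge_position,
                    r.consent_research == "true", r.project, r.sample_type,
                    parse_date(r.creation_date or None), r.description,
                )
            )
        return store


@dataclass
class SyncState:
    """Watermark of the incremental sync; the timestamp never decreases."""

    last_sync_timestamp: _dt.datetime = _dt.datetime(1970, 1, 1)
    processed_ids: set[str] = field(default_factory=set)

    def advance(self, ts: _dt.datetime) -> None:
        if ts > self.last_sync_timestamp:
            self.last_sync_timestamp = ts


@dataclass
class SyncResult:
    store: "BiobankStore"
    state: SyncState
    new_samples: int = 0
    skipped_no_consent: int = 0
    quarantined: list[str] = field(default_factory=list)


def _next_position(n: int) -> str:
    # deterministic rack/shelf/box walk over a 12x4x100 freezer layout
    box, slot = divmod(n, 100)
    shelf, box = divmod(box, 4)
    rack, shelf = divmod(shelf, 12)
    return f"R{rack + 1:02d}-S{shelf + 1}-B{box + 1}-P{slot + 1:03d}"


def sync_pu_to_biobank(
    pu_records: list[PuSpecimenRecord],
    biobank_store: BiobankStore,
    lookup: LookupTable,
    state: SyncState,
    rng: random.Random,
) -> SyncResult:
    """Incremental pathology-unit -> biobank synchronization.

    Only rows newer than the state watermark are considered; consented
    specimens get a fresh barcode and a lookup link, non-consented ones are
    skipped, malformed rows are quarantined with a log line and the sync
    continues.  Re-running with an unchanged source is a no-op.
    """
    result = SyncResult(biobank_store, state)
    max_ts = state.last_sync_timestamp
    for rec in sorted(
        pu_records,
        key=lambda r: (r.updated_at or _dt.datetime.min, r.specimen_id),
    ):
        ts = rec.updated_at
        if ts is None or not rec.pu_patient_id or not rec.specimen_id:
            msg = f"malformed PU record (specimen {rec.specimen_id!r}): missing key field"
            logger.warning(msg)
            result.quarantined.append(msg)
            continue
        if ts <= state.last_sync_timestamp or rec.specimen_id in state.processed_ids:
            continue
        if rec.material_type not in MATERIAL_TYPES:
            msg = f"malformed PU record (specimen {rec.specimen_id!r}): " \
                  f"unknown material {rec.material_type!r}"
            logger.warning(msg)
            result.quarantined.append(msg)
            state.processed_ids.add(rec.specimen_id)
            max_ts = max(max_ts, ts)
            continue
        state.processed_ids.add(rec.specimen_id)
        max_ts = max(max_ts, ts)
        if not rec.consent_research:
            result.skipped_no_consent += 1
            continue
        barcode = new_barcode(lookup, rng)
        lookup.link(rec.pu_patient_id, barcode)
        biobank_store.add(
            BiobankSample(
                payload=str(barcode),
                material_type=rec.material_type,
                fridge_position=_next_position(len(biobank_store)),
                consent_research=True,
                project=rec.project,
                sample_type=rec.sample_type,
                creation_date=rec.collected_date,
                description=rec.description,
            )
        )
        result.new_samples += 1
    state.advance(max_ts)
    return result


# --------------------------------------------------------------------------
# concept dimension
# --------------------------------------------------------------------------

def build_concept_dimension(
    source: ontology.OntologySource | None = None,
) -> list[ConceptRecord]:
    """The full queryable hierarchy: the morphology subtree under
    ``\\SNOMED\\`` plus the internal branches for TNM components,
    biomarkers, biobank materials/meta-attributes and demographics."""
    from .nlp import M_VALUES, N_VALUES, T_VALUES

    if source is None:
        source = ontology.load_packaged_tree()
    concepts: list[ConceptRecord] = []

    concepts.append(ontology.make_branch_root("SNOMED", "SNOMED", "ROOT:SNOMED"))
    concepts.extend(ontology.build_concepts(source.root, "\\SNOMED\\", "SNOMED"))

    concepts.append(ontology.make_branch_root("TNM", "TNM", "ROOT:TNM"))
    for axis, values in (("T", T_VALUES), ("N", N_VALUES), ("M", M_VALUES)):
        concepts.append(
            ConceptRecord(f"ROOT:TNM:{axis}", f"\\TNM\\{axis}\\", axis, 2, "TNM")
        )
        for v in values:
            concepts.append(
                ConceptRecord(
                    f"TNM:{axis}{v}", f"\\TNM\\{axis}\\{axis}{v}\\",
                    f"{axis}{v}", 3, "TNM",
                )
            )

    concepts.append(ontology.make_branch_root("Biomarkers", "BIOMARKER", "ROOT:BIO"))
    for code, name in (
        ("BIO:ER", "Estrogen receptor"),
        ("BIO:PR", "Progesterone receptor"),
        ("BIO:KI67", "Ki-67"),
        ("BIO:HER2", "HER-2 score"),
        ("BIO:GRADE", "Grade"),
    ):
        concepts.append(
            ConceptRecord(code, f"\\Biomarkers\\{name}\\", name, 2, "BIOMARKER")
        )

    concepts.append(ontology.make_branch_root("Biobank", "BIOBANK", "ROOT:BB"))
    for mat in MATERIAL_TYPES:
        concepts.append(
            ConceptRecord(f"BB:{mat}", f"\\Biobank\\{mat}\\", mat, 2, "BIOBANK")
        )
    concepts.append(
        ConceptRecord("ROOT:BB:PRJ", "\\Biobank\\Project\\", "Project", 2, "BIOBANK")
    )
    for prj in PROJECTS:
        concepts.append(
            ConceptRecord(f"BBPRJ:{prj}", f"\\Biobank\\Project\\{prj}\\", prj, 3, "BIOBANK")
        )
    concepts.append(
        ConceptRecord("ROOT:BB:ST", "\\Biobank\\Sample type\\", "Sample type", 2, "BIOBANK")
    )
    for st in SAMPLE_TYPES:
        concepts.append(
            ConceptRecord(f"BBST:{st}", f"\\Biobank\\Sample type\\{st}\\", st, 3, "BIOBANK")
        )

    concepts.append(
        ontology.make_branch_root("Demographics", "DEMOGRAPHIC", "ROOT:DEM")
    )
    concepts.append(
        ConceptRecord("ROOT:DEM:SEX", "\\Demographics\\Sex\\", "Sex", 2, "DEMOGRAPHIC")
    )
    for code, name in _SEX_NAMES.items():
        concepts.append(
            ConceptRecord(f"DEM:SEX:{code}", f"\\Demographics\\Sex\\{name}\\",
                          name, 3, "DEMOGRAPHIC")
        )
    concepts.append(
        ConceptRecord("ROOT:DEM:VITAL", "\\Demographics\\Vital status\\",
                      "Vital status", 2, "DEMOGRAPHIC")
    )
    for code, name in _VITAL_NAMES.items():
        concepts.append(
            ConceptRecord(f"DEM:VITAL:{code}",
                          f"\\Demographics\\Vital status\\{name}\\",
                          name, 3, "DEMOGRAPHIC")
        )
    return concepts


# --------------------------------------------------------------------------
# warehouse load
# --------------------------------------------------------------------------

@dataclass
class HisBundle:
    """What the hospital information system contributes to the load:
    demographics, visits, and the report/patient crosswalks."""

    patients: list[PatientRecord] = field(default_factory=list)
    visits: list[VisitRecord] = field(default_factory=list)
    report_index: dict[str, tuple[str, str]] = field(default_factory=dict)
    pu_to_patient: dict[str, str] = field(default_factory=dict)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            [
                {
                    "patient_id": p.patient_id,
                    "sex": p.sex,
                    "birth_date": p.birth_date.isoformat() if p.birth_date else "",
                    "vital_status": p.vital_status,
                    "death_date": p.death_date.isoformat() if p.death_date else "",
                }
                for p in self.patients
            ],
            columns=["patient_id", "sex", "birth_date", "vital_status", "death_date"],
        ).to_csv(directory / "his_patients.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "visit_id": v.visit_id,
                    "patient_id": v.patient_id,
                    "start_date": v.start_date.isoformat() if v.start_date else "",
                    "end_date": v.end_date.isoformat() if v.end_date else "",
                    "location_code": v.location_code,
                }
                for v in self.visits
            ],
            columns=["visit_id", "patient_id", "start_date", "end_date", "location_code"],
        ).to_csv(directory / "his_visits.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {"report_id": rid, "patient_id": pid, "visit_id": vid}
                for rid, (pid, vid) in sorted(self.report_index.items())
            ],
            columns=["report_id", "patient_id", "visit_id"],
        ).to_csv(directory / "report_index.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {"pu_patient_id": pu, "patient_id": pid}
                for pu, pid in sorted(self.pu_to_patient.items())
            ],
            columns=["pu_patient_id", "patient_id"],
        ).to_csv(directory / "pu_to_patient.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "HisBundle":
        directory = Path(directory)
        read = lambda n: pd.read_csv(
            directory / f"{n}.tsv", sep="\t", dtype=str, keep_default_na=False
        )
        bundle = cls()
        for r in read("his_patients").itertuples(index=False):
            bundle.patients.append(
                PatientRecord(r.patient_id, r.sex, r.birth_date or None,
                              r.vital_status, r.death_date or None)
            )
        for r in read("his_visits").itertuples(index=False):
            bundle.visits.append(
                VisitRecord(r.visit_id, r.patient_id, r.start_date or None,
                            r.end_date or None, r.location_code)
            )
        for r in read("report_index").itertuples(index=False):
            bundle.report_index[r.report_id] = (r.patient_id, r.visit_id)
        for r in read("pu_to_patient").itertuples(index=False):
            bundle.pu_to_patient[r.pu_patient_id] = r.patient_id
        return bundle


@dataclass
class LoadReport:
    facts_written: int = 0
    skipped: int = 0
    orphans: int = 0
    quarantined: int = 0
    messages: list[str] = field(default_factory=list)

    def summary(self) -> dict[str, int]:
        return {
            "facts_written": self.facts_written,
            "skipped": self.skipped,
            "orphans": self.orphans,
            "quarantined": self.quarantined,
        }


class _InstanceCounter:
    """Deterministic instance numbers for repeated (patient, visit,
    concept, date) facts; reset per load so re-runs produce identical keys."""

    def __init__(self):
        self._seen: dict[tuple, int] = {}

    def next(self, patient_id, visit_id, code, date) -> int:
        key = (patient_id, visit_id, code, date)
        self._seen[key] = self._seen.get(key, 0) + 1
        return self._seen[key]


def load_warehouse(
    biobank_store: BiobankStore,
    his: HisBundle,
    extraction_results: list[ExtractionResult],
    concepts: list[ConceptRecord],
    warehouse: Warehouse,
    lookup: LookupTable | None = None,
) -> LoadReport:
    """Merge all sources into the star schema.

    Mapping rules: HIS visits become visit-dimension rows; sex and vital
    status become demographic facts at the patient's first visit; each
    extracted report contributes one fact per morphology code, one per TNM
    component, and one numeric fact per biomarker; each consented biobank
    sample contributes a material fact (text value = payload) plus project
    and sample-type meta facts.  Unknown morphology codes are logged and
    skipped; reports or samples that cannot be tied to a HIS patient are
    counted as orphans.
    """
    report = LoadReport()
    counter = _InstanceCounter()

    warehouse.add_concepts(concepts)
    for prov in PROVIDERS:
        warehouse.add_provider(prov)
    for p in his.patients:
        warehouse.add_patient(p)
    for v in his.visits:
        warehouse.add_visit(v)

    codes = warehouse.concept_codes()
    first_visit: dict[str, VisitRecord] = {}
    visits_by_patient: dict[str, list[VisitRecord]] = {}
    for v in sorted(his.visits, key=lambda v: (v.start_date or _dt.date.min, v.visit_id)):
        visits_by_patient.setdefault(v.patient_id, []).append(v)
        first_visit.setdefault(v.patient_id, v)

    def put(fact: ObservationFact) -> None:
        warehouse.upsert_fact(fact)
        report.facts_written += 1

    # (ii) demographics
    for p in his.patients:
        visit = first_visit.get(p.patient_id)
        if visit is None:
            report.orphans += 1
            report.messages.append(f"patient {p.patient_id} has no visits")
            continue
        for code in (f"DEM:SEX:{p.sex}", f"DEM:VITAL:{p.vital_status}"):
            put(
                ObservationFact(
                    p.patient_id, visit.visit_id, code, "PROV-ONC",
                    visit.start_date,
                    instance_num=counter.next(p.patient_id, visit.visit_id,
                                              code, visit.start_date),
                )
            )

    # (iii) extracted reports
    for res in extraction_results:
        loc = his.report_index.get(res.name)
        if loc is None or loc[0] not in warehouse.patients:
            report.orphans += 1
            report.messages.append(f"report {res.name}: no HIS patient")
            continue
        patient_id, visit_id = loc
        date = res.date

        def fact(code, value_type="none", numeric=None, text=None, units=""):
            put(
                ObservationFact(
                    patient_id, visit_id, code, "PROV-PU", date,
                    value_type, numeric, text, units,
                    counter.next(patient_id, visit_id, code, date),
                )
            )

        for code, _name in res.snomed:
            if code not in codes:
                report.skipped += 1
                report.messages.append(
                    f"report {res.name}: unknown code {code} skipped"
                )
                continue
            fact(code)
        for code in res.unknown_codes:
            report.skipped += 1
            report.messages.append(f"report {res.name}: unknown code {code} skipped")
        if res.state is not None:
            fact(f"TNM:T{res.state.t}")
            fact(f"TNM:N{res.state.n}")
            fact(f"TNM:M{res.state.m}")
        if res.estrogens_receptors is not None:
            fact("BIO:ER", "numeric", res.estrogens_receptors, units="%")
        elif res.er_status is not None:
            fact("BIO:ER", "text", text=res.er_status)
        if res.progesterone_receptors is not None:
            fact("BIO:PR", "numeric", res.progesterone_receptors, units="%")
        elif res.pr_status is not None:
            fact("BIO:PR", "text", text=res.pr_status)
        if res.ki67 is not None:
            fact("BIO:KI67", "numeric", res.ki67, units="%")
        if res.c_erb_b2 is not None:
            fact("BIO:HER2", "numeric", res.c_erb_b2)
        if res.grade is not None:
            fact("BIO:GRADE", "numeric", res.grade)

    # (iv) biobank samples
    for sample in sorted(biobank_store, key=lambda s: s.payload):
        if not sample.consent_research:
            report.skipped += 1
            report.messages.append(f"sample {sample.payload}: no research consent")
            continue
        patient_id = None
        if lookup is not None:
            try:
                pu_id = lookup.resolve(sample.payload, authorized=True)
                patient_id = his.pu_to_patient.get(pu_id)
            except KeyError:
                patient_id = None
        if patient_id is None or patient_id not in warehouse.patients:
            report.orphans += 1
            report.messages.append(f"sample {sample.payload}: no HIS patient")
            continue
        visit = next(
            (v for v in visits_by_patient.get(patient_id, [])
             if v.start_date == sample.creation_date),
            first_visit.get(patient_id),
        )
        if visit is None:
            report.orphans += 1
            report.messages.append(f"sample {sample.payload}: patient has no visits")
            continue
        date = sample.creation_date
        for code, text in (
            (f"BB:{sample.material_type}", sample.payload),
            (f"BBPRJ:{sample.project}", None),
            (f"BBST:{sample.sample_type}", None),
        ):
            if code not in codes:
                report.skipped += 1
                report.messages.append(
                    f"sample {sample.payload}: unknown concept {code} skipped"
                )
                continue
            put(
                ObservationFact(
                    patient_id, visit.visit_id, code, "PROV-BB", date,
                    "text" if text else "none", None, text, "",
                    counter.next(patient_id, visit.visit_id, code, date),
                )
            )
    return report
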