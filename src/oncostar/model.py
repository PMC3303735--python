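"""Star-schema clinical research warehouse.

One central observation-fact table plus four dimension tables — patients,
visits, providers and medical concepts — following the classic clinical
research chart layout.  Concepts carry backslash-delimited hierarchical
paths (leading and trailing delimiter), which drive prefix-based query
expansion.  The warehouse is a plain in-memory container with a delimited
text (TSV) import/export round-trip; no database server is involved.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "PatientRecord",
    "VisitRecord",
    "ProviderRecord",
    "ConceptRecord",
    "ObservationFact",
    "Warehouse",
    "Violation",
    "IntegrityError",
    "PATH_SEP",
    "parse_date",
    "path_level",
    "parent_path",
]

PATH_SEP = "\\"

SEXES = ("F", "M", "U")
VITAL_STATUSES = ("alive", "deceased", "unknown")
CONCEPT_SOURCES = (
    "SNOMED",
    "TNM",
    "BIOMARKER",
    "BIOBANK",
    "DEMOGRAPHIC",
    "VISIT",
    "OTHER",
)
VALUE_TYPES = ("none", "numeric", "text")


class IntegrityError(ValueError):
    """A record violates referential integrity or a table invariant."""


def parse_date(value) -> _dt.date | None:
    """Parse an ISO-8601 date (or pass through a date); empty/None -> None."""
    if value is None or value == "":
        return None
    if isinstance(value, _dt.datetime):
        return value.date()
    if isinstance(value, _dt.date):
        return value
    return _dt.date.fromisoformat(str(value))


def _fmt_date(d: _dt.date | None) -> str:
    return d.isoformat() if d is not None else ""


def path_level(path: str) -> int:
    """Number of segments in a backslash-delimited concept path."""
    return len([s for s in path.split(PATH_SEP) if s])


def parent_path(path: str) -> str:
    """Path with its last segment removed: ``\\A\\B\\`` -> ``\\A\\``."""
    segs = [s for s in path.split(PATH_SEP) if s]
    if len(segs) <= 1:
        return PATH_SEP
    return PATH_SEP + PATH_SEP.join(segs[:-1]) + PATH_SEP


def _check_path(path: str) -> None:
    if not (path.startswith(PATH_SEP) and path.endswith(PATH_SEP) and len(path) > 1):
        raise ValueError(
            f"concept path must begin and end with {PATH_SEP!r}: {path!r}"
        )


@dataclass
class PatientRecord:
    patient_id: str
    sex: str = "U"
    birth_date: _dt.date | None = None
    vital_status: str = "unknown"
    death_date: _dt.date | None = None

    def __post_init__(self):
        self.birth_date = parse_date(self.birth_date)
        self.death_date = parse_date(self.death_date)


@dataclass
class VisitRecord:
    visit_id: str
    patient_id: str
    start_date: _dt.date | None = None
    end_date: _dt.date | None = None
    location_code: str = ""

    def __post_init__(self):
        self.start_date = parse_date(self.start_date)
        self.end_date = parse_date(self.end_date)


@dataclass
class ProviderRecord:
    provider_id: str
    name: str = ""
    department: str = ""


@dataclass
class ConceptRecord:
    concept_code: str
    concept_path: str
    name: str
    level: int = 0
    source: str = "OTHER"

    def __post_init__(self):
        _check_path(self.concept_path)
        if not self.level:
            self.level = path_level(self.concept_path)


@dataclass
class ObservationFact:
    """One coded statement about a patient at a visit.

    ``(patient_id, visit_id, concept_code, obs_date, instance_num)`` is the
    unique key; re-inserting an existing key replaces the stored fact.
    """

    patient_id: str
    visit_id: str
    concept_code: str
    provider_id: str
    obs_date: _dt.date | None = None
    value_type: str = "none"
    numeric_value: float | None = None
    text_value: str | None = None
    units: str = ""
    instance_num: int = 1

    def __post_init__(self):
        self.obs_date = parse_date(self.obs_date)
        if self.numeric_value is not None:
            self.numeric_value = float(self.numeric_value)

    @property
    def key(self) -> tuple:
        return (
            self.patient_id,
            self.visit_id,
            self.concept_code,
            self.obs_date,
            self.instance_num,
        )


@dataclass
class Violation:
    """One integrity-check finding: which table, which key, which rule."""

    table: str
    key: str
    rule: str


@dataclass
class Warehouse:
    """The five star-schema tables as one container."""

    patients: dict[str, PatientRecord] = field(default_factory=dict)
    visits: dict[str, VisitRecord] = field(default_factory=dict)
    providers: dict[str, ProviderRecord] = field(default_factory=dict)
    concepts: dict[str, ConceptRecord] = field(default_factory=dict)  # by path
    facts: dict[tuple, ObservationFact] = field(default_factory=dict)

    # ----------------------------------------------------------- dimensions
    def add_patient(self, rec: PatientRecord) -> None:
        self.patients[rec.patient_id] = rec

    def add_visit(self, rec: VisitRecord) -> None:
        self.visits[rec.visit_id] = rec

    def add_provider(self, rec: ProviderRecord) -> None:
        self.providers[rec.provider_id] = rec

    def add_concept(self, rec: ConceptRecord) -> None:
        self.concepts[rec.concept_path] = rec

    def add_concepts(self, recs: Iterable[ConceptRecord]) -> None:
        for rec in recs:
            self.add_concept(rec)

    def concept_codes(self) -> set[str]:
        return {c.concept_code for c in self.concepts.values()}

    def concepts_by_code(self) -> dict[str, list[ConceptRecord]]:
        out: dict[str, list[ConceptRecord]] = {}
        for c in self.concepts.values():
            out.setdefault(c.concept_code, []).append(c)
        return out

    # ---------------------------------------------------------------- facts
    def upsert_fact(self, fact: ObservationFact, auto_register: bool = False) -> None:
        """Insert or replace one fact (key-idempotent).

        All four foreign keys must resolve; with ``auto_register`` missing
        patients/visits/providers are created as stubs (concepts never are —
        a fact against an unknown concept is always an error).
        """
        if fact.patient_id not in self.patients:
            if auto_register:
                self.add_patient(PatientRecord(fact.patient_id))
            else:
                raise IntegrityError(f"unknown patient_id: {fact.patient_id!r}")
        if fact.visit_id not in self.visits:
            if auto_register:
                self.add_visit(VisitRecord(fact.visit_id, fact.patient_id))
            else:
                raise IntegrityError(f"unknown visit_id: {fact.visit_id!r}")
        if fact.provider_id not in self.providers:
            if auto_register:
                self.add_provider(ProviderRecord(fact.provider_id))
            else:
                raise IntegrityError(f"unknown provider_id: {fact.provider_id!r}")
        if fact.concept_code not in self.concept_codes():
            raise IntegrityError(f"unknown concept_code: {fact.concept_code!r}")
        if fact.value_type == "numeric" and fact.numeric_value is None:
            raise IntegrityError(f"numeric fact without numeric_value: {fact.key}")
        if fact.value_type != "numeric" and fact.numeric_value is not None:
            raise IntegrityError(f"numeric_value on non-numeric fact: {fact.key}")
        self.facts[fact.key] = fact

    # ------------------------------------------------------------ integrity
    def integrity_check(self) -> list[Violation]:
        """Return one descriptor per invariant violation; [] iff consistent."""
        out: list[Violation] = []

        for p in self.patients.values():
            has_death = p.death_date is not None
            if (p.vital_status == "deceased") != has_death:
                out.append(
                    Violation("patients", p.patient_id,
                              "death_date present iff vital_status=deceased")
                )
            if p.birth_date and p.death_date and p.birth_date > p.death_date:
                out.append(
                    Violation("patients", p.patient_id, "birth_date > death_date")
                )
            if p.sex not in SEXES:
                out.append(Violation("patients", p.patient_id, f"bad sex {p.sex!r}"))

        for v in self.visits.values():
            if v.patient_id not in self.patients:
                out.append(
                    Violation("visits", v.visit_id,
                              f"unknown patient_id {v.patient_id!r}")
                )
            if v.start_date and v.end_date and v.start_date > v.end_date:
                out.append(Violation("visits", v.visit_id, "start_date > end_date"))

        paths = set(self.concepts)
        for c in self.concepts.values():
            if c.level != path_level(c.concept_path):
                out.append(
                    Violation("concepts", c.concept_path,
                              "level != number of path segments")
                )
            if path_level(c.concept_path) > 1 and parent_path(c.concept_path) not in paths:
                out.append(
                    Violation("concepts", c.concept_path,
                              f"missing parent {parent_path(c.concept_path)!r}")
                )

        codes = self.concept_codes()
        for f in self.facts.values():
            key = repr(f.key)
            if f.patient_id not in self.patients:
                out.append(Violation("facts", key, f"unknown patient_id {f.patient_id!r}"))
            if f.visit_id not in self.visits:
                out.append(Violation("facts", key, f"unknown visit_id {f.visit_id!r}"))
            if f.provider_id not in self.providers:
                out.append(Violation("facts", key, f"unknown provider_id {f.provider_id!r}"))
            if f.concept_code not in codes:
                out.append(Violation("facts", key, f"unknown concept_code {f.concept_code!r}"))
            if (f.value_type == "numeric") != (f.numeric_value is not None):
                out.append(Violation("facts", key, "numeric_value present iff value_type=numeric"))
            if f.instance_num < 1:
                out.append(Violation("facts", key, "instance_num must be positive"))

        return out

    # --------------------------------------------------------------- counts
    def biobank_codes(self) -> set[str]:
        return {c.concept_code for c in self.concepts.values() if c.source == "BIOBANK"}

    def counts(self) -> dict[str, int]:
        """Cardinality summary, including distinct biobanked patients."""
        bb = self.biobank_codes()
        biobanked = {f.patient_id for f in self.facts.values() if f.concept_code in bb}
        return {
            "n_patients": len(self.patients),
            "n_visits": len(self.visits),
            "n_facts": len(self.facts),
            "n_concepts": len(self.concepts),
            "n_biobanked_patients": len(biobanked),
        }

    # ------------------------------------------------------------------ I/O
    _TABLES = ("patients", "visits", "providers", "concepts", "facts")

    def to_frames(self) -> dict[str, pd.DataFrame]:
        frames = {
            "patients": pd.DataFrame(
                [
                    {
                        "patient_id": p.patient_id,
                        "sex": p.sex,
                        "birth_date": _fmt_date(p.birth_date),
                        "vital_status": p.vital_status,
                        "death_date": _fmt_date(p.death_date),
                    }
                    for p in self.patients.values()
                ],
                columns=["patient_id", "sex", "birth_date", "vital_status", "death_date"],
            ),
            "visits": pd.DataFrame(
                [
                    {
                        "visit_id": v.visit_id,
                        "patient_id": v.patient_id,
                        "start_date": _fmt_date(v.start_date),
                        "end_date": _fmt_date(v.end_date),
                        "location_code": v.location_code,
                    }
                    for v in self.visits.values()
                ],
                columns=["visit_id", "patient_id", "start_date", "end_date", "location_code"],
            ),
            "providers": pd.DataFrame(
                [
                    {"provider_id": p.provider_id, "name": p.name, "department": p.department}
                    for p in self.providers.values()
                ],
                columns=["provider_id", "name", "department"],
            ),
            "concepts": pd.DataFrame(
                [
                    {
                        "concept_code": c.concept_code,
                        "concept_path": c.concept_path,
                        "name": c.name,
                        "level": c.level,
                        "source": c.source,
                    }
                    for c in self.concepts.values()
                ],
                columns=["concept_code", "concept_path", "name", "level", "source"],
            ),
            "facts": pd.DataFrame(
                [
                    {
                        "patient_id": f.patient_id,
                        "visit_id": f.visit_id,
                        "concept_code": f.concept_code,
                        "provider_id": f.provider_id,
                        "obs_date": _fmt_date(f.obs_date),
                        "value_type": f.value_type,
                        "numeric_value": "" if f.numeric_value is None else repr(f.numeric_value),
                        "text_value": "" if f.text_value is None else f.text_value,
                        "units": f.units,
                        "instance_num": f.instance_num,
                    }
                    for f in self.facts.values()
                ],
                columns=[
                    "patient_id", "visit_id", "concept_code", "provider_id",
                    "obs_date", "value_type", "numeric_value", "text_value",
                    "units", "instance_num",
                ],
            ),
        }
        return frames

    def export_dir(self, directory: str | Path) -> None:
        """Write the five tables as UTF-8 tab-separated files with headers."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, frame in self.to_frames().items():
            frame.to_csv(directory / f"{name}.tsv", sep="\t", index=False)

    @classmethod
    def import_dir(cls, directory: str | Path) -> "Warehouse":
        directory = Path(directory)
        read = lambda n: pd.read_csv(
            directory / f"{n}.tsv", sep="\t", dtype=str, keep_default_na=False
        )
        wh = cls()
        for r in read("patients").itertuples(index=False):
            wh.add_patient(
                PatientRecord(r.patient_id, r.sex, r.birth_date or None,
                              r.vital_status, r.death_date or None)
            )
        for r in read("visits").itertuples(index=False):
            wh.add_visit(
                VisitRecord(r.visit_id, r.patient_id, r.start_date or None,
                            r.end_date or None, r.location_code)
            )
        for r in read("providers").itertuples(index=False):
            wh.add_provider(ProviderRecord(r.provider_id, r.name, r.department))
        for r in read("concepts").itertuples(index=False):
            wh.add_concept(
                ConceptRecord(r.concept_code, r.concept_path, r.name,
                              int(r.level), r.source)
            )
        for r in read("facts").itertuples(index=False):
            fact = ObservationFact(
                r.patient_id, r.visit_id, r.concept_code, r.provider_id,
                r.obs_date or None, r.value_type,
                float(r.numeric_value) if r.numeric_value else None,
                r.text_value or None, r.units, int(r.instance_num),
            )
            wh.facts[fact.key] = fact
        return wh
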