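"""Panel-based boolean patient-set queries.

Semantics follow the classic clinical-research-chart panel model: a query
is an ordered list of panels ANDed together; within a panel the listed
concept paths are ORed, each expanded to all hierarchy descendants; a
panel may carry a numeric value constraint and a date range, both bound to
the same fact that matched the concept; a panel may be inverted (patients
NOT matching).  Results are patient-level sets with provenance, and round-
trip through a plain-text export (one id per line under a provenance
header).
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

from .model import ConceptRecord, Warehouse, parse_date
from .ontology import descendants

__all__ = [
    "ValueConstraint",
    "QueryPanel",
    "QueryDefinition",
    "PatientSet",
    "QueryTypeError",
    "PatientSetParseError",
    "eval_panel",
    "run_query",
    "save_patient_set",
    "load_patient_set",
]

_OPERATORS = (">=", "<=", "=", "between")


class QueryTypeError(TypeError):
    """A value constraint was applied to a non-numeric observation."""


class PatientSetParseError(ValueError):
    """A patient-set file is malformed or truncated."""


@dataclass(frozen=True)
class ValueConstraint:
    operator: str
    bounds: tuple[float, ...]

    def __post_init__(self):
        if self.operator not in _OPERATORS:
            raise ValueError(f"unknown operator {self.operator!r}")
        need = 2 if self.operator == "between" else 1
        if len(self.bounds) != need:
            raise ValueError(f"{self.operator!r} needs {need} bound(s)")
        if self.operator == "between" and self.bounds[0] > self.bounds[1]:
            raise ValueError("between bounds must be ordered")

    def matches(self, value: float) -> bool:
        if self.operator == ">=":
            return value >= self.bounds[0]
        if self.operator == "<=":
            return value <= self.bounds[0]
        if self.operator == "=":
            return value == self.bounds[0]
        return self.bounds[0] <= value <= self.bounds[1]


@dataclass
class QueryPanel:
    items: list[str]
    value_constraint: ValueConstraint | None = None
    date_range: tuple[_dt.date | None, _dt.date | None] | None = None
    invert: bool = False

    def __post_init__(self):
        if not self.items:
            raise ValueError("panel needs at least one concept path")


@dataclass
class QueryDefinition:
    panels: list[QueryPanel]

    def __post_init__(self):
        if not self.panels:
            raise ValueError("query needs at least one panel")


@dataclass
class PatientSet:
    patient_ids: set[str]
    provenance: dict = field(default_factory=dict)


def eval_panel(
    panel: QueryPanel, warehouse: Warehouse, concepts: list[ConceptRecord]
) -> set[str]:
    """Patients having >=1 fact under any of the panel's concept paths that
    satisfies the value and date constraints; inverted panels complement
    against the whole patient dimension."""
    codes: set[str] = set()
    for path in panel.items:
        codes.update(c.concept_code for c in descendants(concepts, path))

    lo, hi = (None, None)
    if panel.date_range is not None:
        lo, hi = (parse_date(panel.date_range[0]), parse_date(panel.date_range[1]))

    matched: set[str] = set()
    for fact in warehouse.facts.values():
        if fact.concept_code not in codes:
            continue
        if lo is not None and (fact.obs_date is None or fact.obs_date < lo):
            continue
        if hi is not None and (fact.obs_date is None or fact.obs_date > hi):
            continue
        if panel.value_constraint is not None:
            if fact.value_type != "numeric" or fact.numeric_value is None:
                raise QueryTypeError(
                    f"value constraint on non-numeric observation "
                    f"(concept {fact.concept_code})"
                )
            if not panel.value_constraint.matches(fact.numeric_value):
                continue
        matched.add(fact.patient_id)

    if panel.invert:
        return set(warehouse.patients) - matched
    return matched


def run_query(
    definition: QueryDefinition,
    warehouse: Warehouse,
    concepts: list[ConceptRecord],
    created_at: _dt.datetime | None = None,
) -> PatientSet:
    """AND across panels of :func:`eval_panel` results, with provenance."""
    result: set[str] | None = None
    for panel in definition.panels:
        ids = eval_panel(panel, warehouse, concepts)
        result = ids if result is None else (result & ids)
    provenance = {
        "definition": [
            {
                "items": p.items,
                "value_constraint": (
                    {"operator": p.value_constraint.operator,
                     "bounds": list(p.value_constraint.bounds)}
                    if p.value_constraint else None
                ),
                "date_range": (
                    [str(p.date_range[0] or ""), str(p.date_range[1] or "")]
                    if p.date_range else None
                ),
                "invert": p.invert,
            }
            for p in definition.panels
        ],
        "created_at": (created_at or _dt.datetime.now()).isoformat(),
    }
    return PatientSet(result or set(), provenance)


def save_patient_set(patient_set: PatientSet, path: str | Path) -> Path:
    """One patient id per line under '#'-prefixed provenance headers."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("# patient-set v1\n")
        fh.write(f"# provenance: {json.dumps(patient_set.provenance, sort_keys=True)}\n")
        fh.write(f"# count: {len(patient_set.patient_ids)}\n")
        for pid in sorted(patient_set.patient_ids):
            fh.write(pid + "\n")
    return path


def load_patient_set(path: str | Path) -> PatientSet:
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].strip() != "# patient-set v1":
        raise PatientSetParseError(f"{path}: missing patient-set header")
    provenance: dict = {}
    count: int | None = None
    ids: set[str] = set()
    for line in lines[1:]:
        if line.startswith("# provenance:"):
            try:
                provenance = json.loads(line.split(":", 1)[1])
            except json.JSONDecodeError as exc:
                raise PatientSetParseError(f"{path}: bad provenance") from exc
        elif line.startswith("# count:"):
            count = int(line.split(":", 1)[1])
        elif line.startswith("#") or not line.strip():
            continue
        else:
            ids.add(line.strip())
    if count is not None and count != len(ids):
        raise PatientSetParseError(
            f"{path}: truncated set ({len(ids)} ids, header says {count})"
        )
    return PatientSet(ids, provenance)
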