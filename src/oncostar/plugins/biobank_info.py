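"""Biobank Info: list the stored samples behind a previously extracted
patient set, filtered by material type.

The join runs payload -> donor (segregated lookup, authorization-gated)
-> research patient id (pathology-unit crosswalk) -> patient set; the
returned rows carry the anonymized payload and sample attributes, never a
patient identifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from ..anonymize import AuthorizationError, LookupTable
from ..etl import MATERIAL_TYPES, BiobankStore

__all__ = ["SampleRow", "biobank_info"]


@dataclass(frozen=True)
class SampleRow:
    payload: str
    material_type: str
    fridge_position: str
    consent_research: bool
    project: str
    sample_type: str
    creation_date: object
    description: str


def biobank_info(
    patient_ids: set[str],
    material_type: str,
    biobank_store: BiobankStore,
    lookup: LookupTable,
    pu_to_patient: Mapping[str, str],
    authorized: bool = False,
) -> list[SampleRow]:
    """Samples of the given material whose donor is in the patient set."""
    if not authorized:
        raise AuthorizationError("biobank info requires lookup authorization")
    if material_type not in MATERIAL_TYPES:
        raise ValueError(f"unknown material type {material_type!r}")
    rows: list[SampleRow] = []
    for sample in sorted(biobank_store, key=lambda s: s.payload):
        if sample.material_type != material_type:
            continue
        pu_id = lookup.resolve(sample.payload, authorized=True)
        patient_id = pu_to_patient.get(pu_id)
        if patient_id is None or patient_id not in patient_ids:
            continue
        rows.append(
            SampleRow(
                sample.payload, sample.material_type, sample.fridge_position,
                sample.consent_research, sample.project, sample.sample_type,
                sample.creation_date, sample.description,
            )
        )
    return rows
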