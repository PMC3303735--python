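"""Incremental sync, the warehouse load mapping rules, and idempotence."""

import datetime as dt
import random

import pytest

from oncostar import etl, nlp
from oncostar.anonymize import LookupTable
from oncostar.etl import (
    BiobankStore,
    HisBundle,
    PuSpecimenRecord,
    SyncState,
    build_concept_dimension,
    load_warehouse,
    sync_pu_to_biobank,
)
from oncostar.model import PatientRecord, VisitRecord, Warehouse
from oncostar.nlp import ExtractionResult, TnmStage


def specimen(i, consent=True, **kw) -> PuSpecimenRecord:
    base = dict(
        pu_patient_id=f"PU-{i:04d}", specimen_id=f"SP{i:06d}",
        given_name="Anna", family_name="Rossi", material_type="tissue",
        collected_date=dt.date(2010, 1, 1 + i),
        consent_research=consent, project="BRC-CORE",
        sample_type="diagnostic", description="aliquot 1",
        updated_at=dt.datetime(2010, 2, 1, 9, i),
    )
    base.update(kw)
    return PuSpecimenRecord(**base)


class TestSync:
    def test_new_consented_specimens_all_synced(self):
        store, lookup, state = BiobankStore(), LookupTable(), SyncState()
        result = sync_pu_to_biobank([specimen(i) for i in range(5)],
                                    store, lookup, state, random.Random(0))
        assert result.new_samples == 5
        assert len(store) == 5 and len(lookup.by_payload) == 5

    def test_rerun_with_unchanged_source_is_noop(self):
        records = [specimen(i) for i in range(5)]
        store, lookup, state = BiobankStore(), LookupTable(), SyncState()
        sync_pu_to_biobank(records, store, lookup, state, random.Random(0))
        again = sync_pu_to_biobank(records, store, lookup, state,
                                   random.Random(1))
        assert again.new_samples == 0 and len(store) == 5

    def test_consent_filter(self):
        records = [specimen(i, consent=(i != 2)) for i in range(5)]
        store, lookup, state = BiobankStore(), LookupTable(), SyncState()
        result = sync_pu_to_biobank(records, store, lookup, state,
                                    random.Random(0))
        assert result.new_samples == 4
        assert result.skipped_no_consent == 1

    def test_malformed_record_quarantined_sync_continues(self):
        records = [specimen(0), specimen(1, material_type="granite"),
                   specimen(2, updated_at=None)]
        store, lookup, state = BiobankStore(), LookupTable(), SyncState()
        result = sync_pu_to_biobank(records, store, lookup, state,
                                    random.Random(0))
        assert result.new_samples == 1
        assert len(result.quarantined) == 2

    def test_only_records_after_watermark_processed(self):
        store, lookup = BiobankStore(), LookupTable()
        state = SyncState(last_sync_timestamp=dt.datetime(2010, 2, 1, 9, 2))
        result = sync_pu_to_biobank([specimen(i) for i in range(5)],
                                    store, lookup, state, random.Random(0))
        assert result.new_samples == 2  # minutes 3 and 4 only
        assert state.last_sync_timestamp == dt.datetime(2010, 2, 1, 9, 4)

    def test_samples_carry_no_identity_fields(self):
        store, lookup, state = BiobankStore(), LookupTable(), SyncState()
        sync_pu_to_biobank([specimen(0)], store, lookup, state,
                           random.Random(0))
        sample = next(iter(store))
        values = vars(sample).values()
        assert "Anna" not in values and "Rossi" not in values
        assert not any("PU-" in str(v) for v in values)


# --------------------------------------------------------------------------
# warehouse load
# --------------------------------------------------------------------------

@pytest.fixture
def one_patient_setup():
    """One patient, one report (2 codes + Ki-67 + TNM), one tissue sample."""
    his = HisBundle(
        patients=[PatientRecord("P1", "F", "1950-01-01")],
        visits=[VisitRecord("V1", "P1", "2010-03-01", "2010-03-01", "ONC1")],
        report_index={"R1": ("P1", "V1")},
        pu_to_patient={"PU-0001": "P1"},
    )
    result = ExtractionResult(
        name="R1", date=dt.date(2010, 3, 1), type="histological",
        snomed=[("M-85003", "Infiltrating duct carcinoma"),
                ("M-85013", "Comedocarcinoma")],
        ki67=25.0, state=TnmStage("2", "1", "0", "p"),
    )
    store, lookup, state = BiobankStore(), LookupTable(), SyncState()
    sync_pu_to_biobank(
        [specimen(1, collected_date=dt.date(2010, 3, 1))],
        store, lookup, state, random.Random(0),
    )
    return his, result, store, lookup


class TestLoad:
    def test_mapping_rule_fact_arithmetic(self, one_patient_setup):
        his, result, store, lookup = one_patient_setup
        wh = Warehouse()
        report = load_warehouse(store, his, [result],
                                build_concept_dimension(), wh, lookup)
        # 2 demographics + 2 codes + 3 TNM components + Ki-67 + 3 sample facts
        assert report.facts_written == 2 + 2 + 3 + 1 + 3
        assert report.summary()["orphans"] == 0
        assert report.summary()["skipped"] == 0
        assert wh.counts()["n_facts"] == report.facts_written
        assert wh.counts()["n_biobanked_patients"] == 1
        assert wh.integrity_check() == []

    def test_load_twice_identical_counts(self, one_patient_setup):
        his, result, store, lookup = one_patient_setup
        wh = Warehouse()
        concepts = build_concept_dimension()
        load_warehouse(store, his, [result], concepts, wh, lookup)
        before = wh.counts()
        load_warehouse(store, his, [result], concepts, wh, lookup)
        assert wh.counts() == before

    def test_unknown_code_skipped_with_log_line(self, one_patient_setup):
        his, result, store, lookup = one_patient_setup
        result.unknown_codes = ["M-99999"]
        wh = Warehouse()
        report = load_warehouse(store, his, [result],
                                build_concept_dimension(), wh, lookup)
        assert report.skipped == 1
        assert any("M-99999" in m for m in report.messages)

    def test_report_without_his_patient_is_orphan(self, one_patient_setup):
        his, result, store, lookup = one_patient_setup
        orphan = ExtractionResult(name="R9", date=dt.date(2010, 1, 1))
        wh = Warehouse()
        report = load_warehouse(store, his, [result, orphan],
                                build_concept_dimension(), wh, lookup)
        assert report.orphans == 1
        assert any("R9" in m for m in report.messages)

    def test_numeric_biomarker_facts_have_percent_units(self, one_patient_setup):
        his, result, store, lookup = one_patient_setup
        wh = Warehouse()
        load_warehouse(store, his, [result], build_concept_dimension(), wh, lookup)
        ki = [f for f in wh.facts.values() if f.concept_code == "BIO:KI67"]
        assert ki[0].numeric_value == 25.0 and ki[0].units == "%"
        tnm = sorted(f.concept_code for f in wh.facts.values()
                     if f.concept_code.startswith("TNM:"))
        assert tnm == ["TNM:M0", "TNM:N1", "TNM:T2"]

    def test_sample_fact_carries_payload_not_patient(self, one_patient_setup):
        his, result, store, lookup = one_patient_setup
        wh = Warehouse()
        load_warehouse(store, his, [result], build_concept_dimension(), wh, lookup)
        bb = [f for f in wh.facts.values() if f.concept_code == "BB:tissue"]
        assert bb[0].text_value in lookup.by_payload
        assert "PU-" not in bb[0].text_value


class TestEndToEndConservation:
    def test_pipeline_counts_equal_ground_truth(self, pipeline):
        assert pipeline.warehouse.counts() == \
            pipeline.cohort.truth.expected_counts
        assert pipeline.load_report.summary()["orphans"] == 0
        assert pipeline.load_report.summary()["skipped"] == 0

    def test_his_bundle_round_trip(self, tmp_path, pipeline):
        pipeline.cohort.his.save(tmp_path)
        back = HisBundle.load(tmp_path)
        assert back.report_index == pipeline.cohort.his.report_index
        assert back.pu_to_patient == pipeline.cohort.his.pu_to_patient
        assert back.patients == pipeline.cohort.his.patients
        assert back.visits == pipeline.cohort.his.visits

    def test_biobank_store_round_trip(self, tmp_path, pipeline):
        pipeline.store.save(tmp_path)
        back = BiobankStore.load(tmp_path)
        assert back.samples == pipeline.store.samples
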