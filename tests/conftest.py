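"""Shared fixtures: small synthetic cohorts run through the full pipeline,
plus independent brute-force oracles for query evaluation."""

from __future__ import annotations

import random
from dataclasses import dataclass

import pytest

from oncostar import etl, nlp, synthetic
from oncostar.anonymize import LookupTable
from oncostar.model import PATH_SEP, Warehouse


@dataclass
class Pipeline:
    """Everything produced by one simulate -> extract -> sync -> load run."""

    cohort: synthetic.SimulatedCohort
    config: nlp.ExtractionConfig
    results: list[nlp.ExtractionResult]
    store: etl.BiobankStore
    lookup: LookupTable
    state: etl.SyncState
    warehouse: Warehouse
    load_report: etl.LoadReport

    @property
    def concepts(self):
        return list(self.warehouse.concepts.values())


def run_pipeline(n_patients: int, seed: int, noise: str = "none",
                 biobank_fraction: float | None = None) -> Pipeline:
    params = synthetic.CohortParams(
        n_patients=n_patients, seed=seed, noise_level=noise,
        **({"biobank_fraction": biobank_fraction}
           if biobank_fraction is not None else {}),
    )
    cohort = synthetic.simulate_cohort(params)
    config = nlp.default_config()
    results = [
        nlp.extract_report(text, config)
        for _, text in sorted(cohort.report_texts.items())
    ]
    store, lookup, state = etl.BiobankStore(), LookupTable(), etl.SyncState()
    etl.sync_pu_to_biobank(cohort.pu_records, store, lookup, state,
                           random.Random(seed))
    warehouse = Warehouse()
    report = etl.load_warehouse(
        store, cohort.his, results, etl.build_concept_dimension(),
        warehouse, lookup,
    )
    return Pipeline(cohort, config, results, store, lookup, state,
                    warehouse, report)


@pytest.fixture(scope="session")
def pipeline() -> Pipeline:
    """A mid-sized cohort (enough biobanked patients to exercise joins)."""
    return run_pipeline(n_patients=200, seed=11)


@pytest.fixture(scope="session")
def warehouse(pipeline) -> Warehouse:
    return pipeline.warehouse


# --------------------------------------------------------------------------
# independent query oracle: a literal scan over the raw fact table
# --------------------------------------------------------------------------

def _path_matches(concept_path: str, item: str) -> bool:
    if not item.endswith(PATH_SEP):
        item += PATH_SEP
    return concept_path.startswith(item)


def oracle_eval_panel(panel, warehouse, concepts) -> set[str]:
    code_paths = {}
    for c in concepts:
        code_paths.setdefault(c.concept_code, []).append(c.concept_path)
    hits: set[str] = set()
    for fact in warehouse.facts.values():
        in_panel = any(
            _path_matches(p, item)
            for p in code_paths.get(fact.concept_code, [])
            for item in panel.items
        )
        if not in_panel:
            continue
        if panel.date_range is not None:
            lo, hi = panel.date_range
            if lo is not None and (fact.obs_date is None or fact.obs_date < lo):
                continue
            if hi is not None and (fact.obs_date is None or fact.obs_date > hi):
                continue
        if panel.value_constraint is not None:
            if fact.value_type != "numeric":
                raise TypeError("value constraint on non-numeric fact")
            if not panel.value_constraint.matches(fact.numeric_value):
                continue
        hits.add(fact.patient_id)
    return (set(warehouse.patients) - hits) if panel.invert else hits


def oracle_run_query(definition, warehouse, concepts) -> set[str]:
    out = None
    for panel in definition.panels:
        ids = oracle_eval_panel(panel, warehouse, concepts)
        out = ids if out is None else out & ids
    return out or set()


def random_definition(rng: random.Random, concepts, numeric_paths):
    """A randomized query over the real concept dimension; value
    constraints only ever target numeric biomarker concepts."""
    from oncostar.query import QueryDefinition, QueryPanel, ValueConstraint

    all_paths = [c.concept_path for c in concepts]
    panels = []
    for _ in range(rng.randint(1, 3)):
        constraint = None
        date_range = None
        if rng.random() < 0.30:
            items = [rng.choice(numeric_paths)]
            op = rng.choice((">=", "<=", "=", "between"))
            if op == "between":
                a, b = sorted((rng.uniform(0, 100), rng.uniform(0, 100)))
                constraint = ValueConstraint(op, (a, b))
            else:
                constraint = ValueConstraint(op, (rng.uniform(0, 100),))
        else:
            items = rng.sample(all_paths, rng.randint(1, 3))
        if rng.random() < 0.25:
            import datetime as dt
            lo = dt.date(2001, 1, 1) + dt.timedelta(days=rng.randint(0, 3000))
            hi = lo + dt.timedelta(days=rng.randint(30, 2000))
            date_range = (lo, hi)
        panels.append(QueryPanel(items, constraint, date_range,
                                 invert=rng.random() < 0.20))
    return QueryDefinition(panels)
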