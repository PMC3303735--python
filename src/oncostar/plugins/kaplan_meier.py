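"""Kaplan-Meier product-limit survival estimation.

Given right-censored time-to-event records, the survivor function is
estimated as

    S(t) = prod_{t_i <= t} (1 - d_i / n_i)

over the distinct observed event times t_i, where d_i is the number of
events at t_i and n_i the number at risk just before t_i.  Censored
observations tied with an event time are counted at risk *through* that
time (the standard convention).  The median is the first time at which
S drops to 0.5 or below, undefined if it never does.

Index dates, when deriving records from the warehouse, are each patient's
first morphology-coded diagnosis fact; the endpoint is overall survival
(death from the patient dimension), with administrative censoring at a
caller-supplied date.  Greenwood standard errors are available but off by
default.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from pathlib import Path

from ..model import PATH_SEP, Warehouse

__all__ = [
    "SurvivalRecord",
    "SurvivalCurve",
    "kaplan_meier",
    "survival_from_warehouse",
    "export_curve",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """Follow-up for one patient: days from index date, and whether death
    was observed (False = censored at ``time``)."""

    patient_id: str
    time: float
    event: bool

    def __post_init__(self):
        if self.time < 0:
            raise ValueError(f"negative follow-up time for {self.patient_id}")


@dataclass
class SurvivalCurve:
    """Step-function estimate: one entry per distinct event time."""

    times: list[float]
    survival: list[float]
    at_risk: list[int]
    events: list[int]
    n_total: int
    median: float | None = None
    std_err: list[float] | None = None  # Greenwood, optional

    def survival_at(self, t: float) -> float:
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return s


def kaplan_meier(
    records: list[SurvivalRecord], greenwood: bool = False
) -> SurvivalCurve:
    """Product-limit estimate over ``records`` (non-empty)."""
    if not records:
        raise ValueError("no survival records")

    event_times = sorted({r.time for r in records if r.event})
    times: list[float] = []
    survival: list[float] = []
    at_risk: list[int] = []
    events: list[int] = []
    s = 1.0
    var_acc = 0.0
    std_err: list[float] = []
    for t in event_times:
        n_i = sum(1 for r in records if r.time >= t)
        d_i = sum(1 for r in records if r.event and r.time == t)
        s *= 1.0 - d_i / n_i
        times.append(t)
        survival.append(s)
        at_risk.append(n_i)
        events.append(d_i)
        if greenwood:
            if n_i > d_i:
                var_acc += d_i / (n_i * (n_i - d_i))
                std_err.append(s * math.sqrt(var_acc))
            else:
                std_err.append(0.0)

    median = next((t for t, si in zip(times, survival) if si <= 0.5), None)
    return SurvivalCurve(
        times, survival, at_risk, events, len(records), median,
        std_err if greenwood else None,
    )


def survival_from_warehouse(
    warehouse: Warehouse,
    censor_date: _dt.date,
    patient_ids: set[str] | None = None,
    index_branch: str = PATH_SEP + "SNOMED" + PATH_SEP,
) -> list[SurvivalRecord]:
    """Build overall-survival records from the star schema.

    Index date = the patient's earliest fact under ``index_branch`` (first
    coded diagnosis); deceased patients contribute an event at death,
    others are censored at ``censor_date``.  Patients with no index fact
    are left out.
    """
    branch_codes = {
        c.concept_code
        for c in warehouse.concepts.values()
        if c.concept_path.startswith(index_branch)
    }
    index: dict[str, _dt.date] = {}
    for f in warehouse.facts.values():
        if f.concept_code in branch_codes and f.obs_date is not None:
            cur = index.get(f.patient_id)
            if cur is None or f.obs_date < cur:
                index[f.patient_id] = f.obs_date

    out: list[SurvivalRecord] = []
    for pid, idx_date in sorted(index.items()):
        if patient_ids is not None and pid not in patient_ids:
            continue
        patient = warehouse.patients[pid]
        if patient.vital_status == "deceased" and patient.death_date is not None:
            out.append(
                SurvivalRecord(pid, (patient.death_date - idx_date).days, True)
            )
        else:
            out.append(
                SurvivalRecord(pid, (censor_date - idx_date).days, False)
            )
    return out


def export_curve(curve: SurvivalCurve, path: str | Path) -> Path:
    """Write the step function as delimited text
    (time, at_risk, events, survival)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("time\tat_risk\tevents\tsurvival\n")
        for t, n, d, s in zip(curve.times, curve.at_risk, curve.events,
                              curve.survival):
            fh.write(f"{t:g}\t{n}\t{d}\t{s:.10f}\n")
    return path
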