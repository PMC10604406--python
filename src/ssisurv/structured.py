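"""The original structured-data surveillance algorithm (model 1).

Four binary components are evaluated per index surgery over a 45-day
follow-up window (surgery day = day 0):

* **admissions** — index-admission length of stay ≥ 14 days, or ≥ 1
  readmission to the discharging department, or in-hospital death within
  follow-up;
* **re-surgery** — ≥ 1 reoperation by the original surgical specialty
  after the index surgery but within follow-up;
* **radiology** — ≥ 1 CT order within follow-up;
* **antibiotics** — ≥ 3 consecutive calendar days with a systemic
  antibacterial (ATC prefix J01), eligible from day 2 onward.

A surgery fulfilling at least two of the four is classified *high
probability* for deep SSI and routed to manual chart review; the rest
are removed from review, which is where the workload reduction of
semi-automated surveillance comes from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .cohort import (
    AdmissionEvent,
    CohortTable,
    MedicationEvent,
    RadiologyOrder,
    ReoperationEvent,
    SurgeryRecord,
)

logger = logging.getLogger(__name__)

#: Follow-up horizon in days after surgery.
FOLLOW_UP_DAYS = 45
#: Index length-of-stay threshold in days.
LOS_THRESHOLD_DAYS = 14
#: First post-operative day on which antibiotic days become eligible.
ANTIBIOTICS_START_DAY = 2
#: Minimum consecutive antibiotic days.
ANTIBIOTICS_RUN_LENGTH = 3
#: ATC prefix for systemic antibacterials.
ATC_ANTIBACTERIAL_PREFIX = "J01"
#: Number of fulfilled components that classifies a surgery high probability.
HIGH_PROBABILITY_MIN_COMPONENTS = 2


@dataclass(frozen=True)
class StructuredResult:
    surgery_id: str
    admissions_flag: bool
    resurgery_flag: bool
    radiology_flag: bool
    antibiotics_flag: bool

    @property
    def component_count(self) -> int:
        return sum(
            (self.admissions_flag, self.resurgery_flag, self.radiology_flag, self.antibiotics_flag)
        )

    @property
    def high_probability(self) -> bool:
        return self.component_count >= HIGH_PROBABILITY_MIN_COMPONENTS


def _day(surgery: SurgeryRecord, date) -> int:
    return (date - surgery.surgery_date).days


def find_index_admission(
    surgery: SurgeryRecord, admissions: Sequence[AdmissionEvent]
) -> Optional[AdmissionEvent]:
    """The admission whose stay interval contains the surgery date.

    Open admissions (no discharge yet) contain every date from admission
    onward.  If several admissions qualify, the earliest admission wins.
    """
    candidates = [
        a
        for a in admissions
        if a.admit_date <= surgery.surgery_date
        and (a.discharge_date is None or a.discharge_date >= surgery.surgery_date)
    ]
    if not candidates:
        return None
    return min(candidates, key=lambda a: a.admit_date)


def eval_admissions_component(
    surgery: SurgeryRecord, admissions: Sequence[AdmissionEvent]
) -> bool:
    index = find_index_admission(surgery, admissions)
    if index is None:
        logger.warning(
            "surgery %s: no admission contains the surgery date; "
            "admissions component evaluated on readmission/mortality only",
            surgery.surgery_id,
        )
        index_department = surgery.department
        index_discharge = surgery.surgery_date
    else:
        index_department = index.department
        # An admission still open is treated as extending through follow-up.
        index_discharge = index.discharge_date
        los = (
            _day(surgery, index_discharge) - _day(surgery, index.admit_date)
            if index_discharge is not None
            else FOLLOW_UP_DAYS - _day(surgery, index.admit_date)
        )
        if los >= LOS_THRESHOLD_DAYS:
            return True

    for a in admissions:
        if index is not None and a is index:
            continue
        day = _day(surgery, a.admit_date)
        if (
            a.department == index_department
            and (index_discharge is None or a.admit_date > index_discharge)
            and 1 <= day <= FOLLOW_UP_DAYS
        ):
            return True

    for a in admissions:
        if a.died_in_hospital:
            death_date = a.discharge_date if a.discharge_date is not None else a.admit_date
            if 0 <= _day(surgery, death_date) <= FOLLOW_UP_DAYS:
                return True
    return False


def eval_resurgery_component(
    surgery: SurgeryRecord, reoperations: Sequence[ReoperationEvent]
) -> bool:
    return any(
        r.specialty == surgery.specialty and 1 <= _day(surgery, r.operation_date) <= FOLLOW_UP_DAYS
        for r in reoperations
    )


def eval_radiology_component(
    surgery: SurgeryRecord, orders: Sequence[RadiologyOrder]
) -> bool:
    return any(
        o.modality == "CT" and 0 <= _day(surgery, o.order_date) <= FOLLOW_UP_DAYS
        for o in orders
    )


def eval_antibiotics_component(
    surgery: SurgeryRecord, medications: Sequence[MedicationEvent]
) -> bool:
    """≥3 consecutive eligible days with a J01 administration.

    Eligible days are post-operative days 2..45; days 0–1 never
    contribute (perioperative prophylaxis is routine).
    """
    days = sorted(
        {
            _day(surgery, m.administration_date)
            for m in medications
            if m.atc_code.startswith(ATC_ANTIBACTERIAL_PREFIX)
            and ANTIBIOTICS_START_DAY <= _day(surgery, m.administration_date) <= FOLLOW_UP_DAYS
        }
    )
    run = 0
    prev = None
    for d in days:
        run = run + 1 if prev is not None and d == prev + 1 else 1
        if run >= ANTIBIOTICS_RUN_LENGTH:
            return True
        prev = d
    return False


def classify_structured(surgery: SurgeryRecord, cohort: CohortTable) -> StructuredResult:
    """Evaluate all four components and the 2-of-4 high-probability rule."""
    admissions, reoperations, radiology, medications = cohort.events_for(surgery.patient_id)
    return StructuredResult(
        surgery_id=surgery.surgery_id,
        admissions_flag=eval_admissions_component(surgery, admissions),
        resurgery_flag=eval_resurgery_component(surgery, reoperations),
        radiology_flag=eval_radiology_component(surgery, radiology),
        antibiotics_flag=eval_antibiotics_component(surgery, medications),
    )


def run_structured(cohort: CohortTable) -> list[StructuredResult]:
    return [classify_structured(s, cohort) for s in cohort.surgeries]


def results_to_frame(results: Sequence[StructuredResult]) -> pd.DataFrame:
    """One row per surgery with boolean component columns."""
    return pd.DataFrame(
        {
            "surgery_id": [r.surgery_id for r in results],
            "admissions_flag": [r.admissions_flag for r in results],
            "resurgery_flag": [r.resurgery_flag for r in results],
            "radiology_flag": [r.radiology_flag for r in results],
            "antibiotics_flag": [r.antibiotics_flag for r in results],
            "component_count": [r.component_count for r in results],
            "high_probability": [r.high_probability for r in results],
        }
    )
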