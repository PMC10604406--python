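import datetime as dt

import pytest

from ssisurv.cohort import (
    AdmissionEvent,
    ClinicalNote,
    CohortTable,
    MedicationEvent,
    RadiologyOrder,
    ReferenceLabel,
    ReoperationEvent,
    SurgeryRecord,
)
from ssisurv.notes import default_lexicon, default_triggers

SURGERY_DATE = dt.date(2020, 3, 1)


def day(n: int) -> dt.date:
    """Calendar date n days after the reference surgery date."""
    return SURGERY_DATE + dt.timedelta(days=n)


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def triggers():
    return default_triggers()


def make_surgery(sid="s1", pid="p1", specialty="colorectal surgery", department="surgery"):
    return SurgeryRecord(
        surgery_id=sid,
        patient_id=pid,
        surgery_date=SURGERY_DATE,
        specialty=specialty,
        department=department,
    )


@pytest.fixture
def surgery():
    return make_surgery()


def make_cohort(surgery, admissions=(), reoperations=(), radiology=(),
                medications=(), notes=(), labels=None):
    return CohortTable(
        surgeries=[surgery],
        admissions=list(admissions),
        reoperations=list(reoperations),
        radiology=list(radiology),
        medications=list(medications),
        notes=list(notes),
        labels=labels,
    )


@pytest.fixture(scope="session")
def two_surgery_cohort():
    """Tiny hand-built cohort with all six tables, Swedish text included."""
    s1 = make_surgery("s1", "p1")
    s2 = make_surgery("s2", "p2")
    return CohortTable(
        surgeries=[s1, s2],
        admissions=[
            AdmissionEvent("p1", day(-1), day(20), "surgery"),
            AdmissionEvent("p2", day(0), day(4), "surgery"),
        ],
        reoperations=[ReoperationEvent("p1", day(9), "colorectal surgery")],
        radiology=[RadiologyOrder("p1", day(12), "CT")],
        medications=[
            MedicationEvent("p1", day(d), "J01DH02") for d in (4, 5, 6, 7)
        ],
        notes=[
            ClinicalNote("n1", "p1", "s1", day(16), "physician",
                         "abscess i buken, dränage anlagt"),
            ClinicalNote("n2", "p2", "s2", day(5), "nurse",
                         "ingen infektion, mår väl"),
        ],
        labels=[
            ReferenceLabel("s1", True, ssi_onset_day=9),
            ReferenceLabel("s2", False),
        ],
    )
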