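"""Synthetic surveillance cohorts with SSI-dependent structure.

Generates fully artificial cohorts — index surgeries, admissions,
reoperations, radiology orders, antibiotic administrations, reference
labels and keyword-bearing clinical notes — whose statistical structure
matches what the surveillance pipeline assumes: surgeries with deep SSI
have longer stays, more reoperations, more CT orders and longer
antibiotic runs, and their notes mention infection-related keywords more
often, concentrated in post-operative days 15–30.

Notes are keyword/filler token sequences, not fluent prose: enough to
exercise tokenization, proximity matching and negation (a configurable
share of mentions is negated by prefixing a trigger), but nothing about
clinical language style.  The default token mode is Swedish, which keeps
UTF-8 handling honest end to end.

The ``validation-like`` preset reproduces, in expectation, the scale of
a realistic validation cohort: 225 surgeries, deep-SSI prevalence
41/225 ≈ 18%, and per-component event rates of 0.80 (SSI-positive) vs
0.275 (SSI-negative) chosen so that the 2-of-4 structured rule flags
≈ 43% of surgeries (≈ 96/225) and ≈ 98% of the SSI-positive ones.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .cohort import (
    AdmissionEvent,
    ClinicalNote,
    CohortTable,
    MedicationEvent,
    RadiologyOrder,
    ReferenceLabel,
    ReoperationEvent,
    SurgeryRecord,
)
from .notes import Lexicon, default_lexicon

COMPONENTS = ("admissions", "resurgery", "radiology", "antibiotics")
#: Post-operative day bins of the note keyword-emission model.
DAY_BINS = ((1, 7), (8, 14), (15, 30))

#: Keywords that separate the groups strongly (distinctive findings and
#: therapeutic antibiotics); the remaining keywords appear in both groups.
SIGNAL_KEYWORDS = (
    "abscess",
    "anastomotic leakage",
    "drainage",
    "drained",
    "piperacillin-tazobactam",
    "meropenem",
    "imipenem",
    "metronidazole",
    "ciprofloxacin",
    "cefotaxime",
    "trimethoprim-sulfa",
    "cefuroxime",
    "amoxicillin",
)

#: Per-note Poisson emission means per day bin (1–7, 8–14, 15–30).
_SIGNAL_RATES = {"positive": (0.05, 0.20, 0.70), "negative": (0.005, 0.01, 0.02)}
_GENERIC_RATES = {"positive": (0.05, 0.10, 0.30), "negative": (0.02, 0.04, 0.08)}

_FILLERS = {
    "sv": (
        "patienten", "mår", "väl", "efter", "operationen", "idag", "fortsatt",
        "stabil", "vid", "ronden", "planeras", "hemgång", "imorgon",
        "smärtlindring", "fungerar", "bra", "temp", "normal", "cirkulatoriskt",
        "opåverkad", "äter", "dricker",
    ),
    "en": (
        "patient", "doing", "well", "after", "the", "operation", "today",
        "stable", "on", "rounds", "plan", "discharge", "tomorrow", "pain",
        "control", "adequate", "temp", "normal", "eating", "drinking",
    ),
}
_NEGATION_PREFIX = {"sv": "ingen", "en": "no"}


class ConfigError(ValueError):
    """A generator parameter is out of range."""


def default_keyword_rates(lexicon: Optional[Lexicon] = None) -> dict:
    """keyword → {status → per-bin Poisson means} for the given lexicon."""
    lexicon = lexicon if lexicon is not None else default_lexicon()
    return {
        kw: dict(_SIGNAL_RATES if kw in SIGNAL_KEYWORDS else _GENERIC_RATES)
        for kw in lexicon.keywords
    }


#: Strongly separated emission means: under these, nearly every deep-SSI
#: surgery mentions signal keywords in every day bin while SSI-negative
#: surgeries almost never do.  This is the parameter-recovery condition:
#: a pipeline that cannot separate the groups here is broken.
_SEPARATED_SIGNAL_RATES = {"positive": (0.4, 0.8, 1.5), "negative": (0.0, 0.005, 0.01)}
_SEPARATED_GENERIC_RATES = {"positive": (0.2, 0.4, 0.8), "negative": (0.01, 0.02, 0.03)}


def well_separated_keyword_rates(lexicon: Optional[Lexicon] = None) -> dict:
    """Emission rates with near-disjoint keyword behaviour between groups."""
    lexicon = lexicon if lexicon is not None else default_lexicon()
    return {
        kw: dict(
            _SEPARATED_SIGNAL_RATES if kw in SIGNAL_KEYWORDS else _SEPARATED_GENERIC_RATES
        )
        for kw in lexicon.keywords
    }


@dataclass
class GeneratorConfig:
    """Everything the cohort generator draws from; all rates per event."""

    n_surgeries: int = 225
    deep_ssi_prevalence: float = 41 / 225
    component_rates_positive: Mapping[str, float] = field(
        default_factory=lambda: {c: 0.80 for c in COMPONENTS}
    )
    component_rates_negative: Mapping[str, float] = field(
        default_factory=lambda: {c: 0.275 for c in COMPONENTS}
    )
    keyword_rates: Optional[Mapping[str, Mapping[str, Sequence[float]]]] = None
    negation_rate: float = 0.15
    notes_per_surgery_mean: float = 4.0
    language: str = "sv"
    id_prefix: str = "S"
    seed: int = 0

    def validate(self) -> None:
        if self.n_surgeries < 1:
            raise ConfigError(f"n_surgeries must be ≥ 1, got {self.n_surgeries}")
        probs = [self.deep_ssi_prevalence, self.negation_rate]
        probs += list(self.component_rates_positive.values())
        probs += list(self.component_rates_negative.values())
        for p in probs:
            if not 0 <= p <= 1:
                raise ConfigError(f"probability {p} outside [0, 1]")
        for c in COMPONENTS:
            if c not in self.component_rates_positive or c not in self.component_rates_negative:
                raise ConfigError(f"missing component rate for {c!r}")
        if self.notes_per_surgery_mean <= 0:
            raise ConfigError("notes_per_surgery_mean must be positive")
        if self.language not in _FILLERS:
            raise ConfigError(f"language must be one of {tuple(_FILLERS)}")


def preset_validation_like(seed: int = 0) -> GeneratorConfig:
    """Config matching the validation cohort's scale in expectation.

    225 surgeries, prevalence 41/225, and component rates calibrated so
    the structured stage flags ≈ 96/225 ≈ 43% of surgeries.
    """
    cfg = GeneratorConfig(seed=seed)
    cfg.validate()
    return cfg


def _day_bin_index(day: int) -> Optional[int]:
    for i, (lo, hi) in enumerate(DAY_BINS):
        if lo <= day <= hi:
            return i
    return None


def _make_note_text(
    rng: np.random.Generator,
    status: str,
    day: int,
    lexicon: Lexicon,
    keyword_rates: Mapping,
    negation_rate: float,
    language: str,
) -> str:
    fillers = _FILLERS[language]
    neg = _NEGATION_PREFIX[language]
    bin_idx = _day_bin_index(day)
    chunks: list[list[str]] = []
    if bin_idx is not None:
        for entry in lexicon.entries:
            rates = keyword_rates.get(entry.canonical_keyword)
            if rates is None:
                continue
            n_mentions = rng.poisson(rates[status][bin_idx])
            for _ in range(n_mentions):
                variant = entry.variants[rng.integers(0, len(entry.variants))]
                chunk = list(variant.split())
                if entry.requires_proximity:
                    loc = entry.location_terms[rng.integers(0, len(entry.location_terms))]
                    chunk += ["i" if language == "sv" else "in"] + loc.split()
                if rng.random() < negation_rate:
                    chunk = [neg] + chunk
                chunks.append(chunk)
    chunks = [chunks[i] for i in rng.permutation(len(chunks))]
    # ≥6 filler tokens between chunks so one mention's negation trigger
    # cannot spill into the scope of the next mention
    tokens = list(rng.choice(fillers, size=rng.integers(4, 9)))
    for chunk in chunks:
        tokens += chunk
        tokens += list(rng.choice(fillers, size=rng.integers(6, 10)))
    return " ".join(tokens)


def generate_cohort(
    config: GeneratorConfig, lexicon: Optional[Lexicon] = None
) -> CohortTable:
    """Draw a full labelled cohort; byte-identical under a fixed seed."""
    config.validate()
    lexicon = lexicon if lexicon is not None else default_lexicon()
    keyword_rates = (
        config.keyword_rates
        if config.keyword_rates is not None
        else default_keyword_rates(lexicon)
    )
    rng = np.random.default_rng(config.seed)
    base_date = dt.date(2019, 1, 1)

    surgeries, admissions, reoperations = [], [], []
    radiology, medications, notes, labels = [], [], [], []
    note_counter = 0

    for i in range(config.n_surgeries):
        sid = f"{config.id_prefix}{i:05d}"
        pid = f"P-{config.id_prefix}{i:05d}"
        surgery_date = base_date + dt.timedelta(days=int(rng.integers(0, 365)))
        surgeries.append(
            SurgeryRecord(
                surgery_id=sid,
                patient_id=pid,
                surgery_date=surgery_date,
                specialty="colorectal surgery",
                department="surgery",
            )
        )
        is_ssi = bool(rng.random() < config.deep_ssi_prevalence)
        status = "positive" if is_ssi else "negative"
        rates = (
            config.component_rates_positive if is_ssi else config.component_rates_negative
        )
        labels.append(
            ReferenceLabel(
                surgery_id=sid,
                deep_ssi=is_ssi,
                ssi_onset_day=int(rng.integers(3, 31)) if is_ssi else None,
            )
        )

        # --- admissions component -----------------------------------
        admit = surgery_date - dt.timedelta(days=int(rng.integers(0, 4)))
        if rng.random() < rates["admissions"]:
            u = rng.random()
            if u < 0.6:  # prolonged index stay
                los = 14 + int(rng.poisson(7.0))
                admissions.append(
                    AdmissionEvent(pid, admit, admit + dt.timedelta(days=los), "surgery")
                )
            elif u < 0.9:  # readmission to the discharging department
                discharge = surgery_date + dt.timedelta(days=int(rng.integers(3, 8)))
                admissions.append(AdmissionEvent(pid, admit, discharge, "surgery"))
                re_day = int(rng.integers((discharge - surgery_date).days + 1, 46))
                re_admit = surgery_date + dt.timedelta(days=re_day)
                admissions.append(
                    AdmissionEvent(
                        pid, re_admit, re_admit + dt.timedelta(days=int(rng.integers(2, 10))), "surgery"
                    )
                )
            else:  # in-hospital death within follow-up
                death = surgery_date + dt.timedelta(days=int(rng.integers(1, 45)))
                admissions.append(
                    AdmissionEvent(pid, admit, death, "surgery", died_in_hospital=True)
                )
        else:
            discharge = surgery_date + dt.timedelta(days=int(rng.integers(3, 10)))
            admissions.append(AdmissionEvent(pid, admit, discharge, "surgery"))
            if rng.random() < 0.10:  # decoy: readmission to another department
                re_admit = surgery_date + dt.timedelta(days=int(rng.integers(8, 46)))
                admissions.append(
                    AdmissionEvent(
                        pid, re_admit, re_admit + dt.timedelta(days=3), "medicine"
                    )
                )

        # --- re-surgery component -----------------------------------
        if rng.random() < rates["resurgery"]:
            reoperations.append(
                ReoperationEvent(
                    pid,
                    surgery_date + dt.timedelta(days=int(rng.integers(2, 45))),
                    "colorectal surgery",
                )
            )
        elif rng.random() < 0.10:  # decoy: other specialty
            reoperations.append(
                ReoperationEvent(
                    pid,
                    surgery_date + dt.timedelta(days=int(rng.integers(2, 45))),
                    "orthopaedics",
                )
            )

        # --- radiology component ------------------------------------
        if rng.random() < rates["radiology"]:
            radiology.append(
                RadiologyOrder(
                    pid, surgery_date + dt.timedelta(days=int(rng.integers(0, 46))), "CT"
                )
            )
        if rng.random() < 0.20:  # decoy modality either way
            radiology.append(
                RadiologyOrder(
                    pid,
                    surgery_date + dt.timedelta(days=int(rng.integers(0, 46))),
                    str(rng.choice(["MRI", "ultrasound", "X-ray"])),
                )
            )

        # --- antibiotics component ----------------------------------
        if rng.random() < 0.8:  # routine perioperative prophylaxis, never counted
            medications.append(MedicationEvent(pid, surgery_date, "J01DC02"))
        if rng.random() < rates["antibiotics"]:
            start = int(rng.integers(2, 41))
            run = 3 + int(rng.poisson(2.0))
            code = str(rng.choice(["J01DH02", "J01CR05", "J01XD01", "J01MA02"]))
            for d in range(start, min(start + run, 46)):
                medications.append(
                    MedicationEvent(pid, surgery_date + dt.timedelta(days=d), code)
                )
        elif rng.random() < 0.25:  # decoy: isolated doses, gaps ≥ 2 days
            days = rng.choice(np.arange(2, 46, 3), size=int(rng.integers(1, 4)), replace=False)
            for d in sorted(int(x) for x in days):
                medications.append(
                    MedicationEvent(pid, surgery_date + dt.timedelta(days=d), "J01MA02")
                )

        # --- clinical notes -----------------------------------------
        n_notes = max(1, int(rng.poisson(config.notes_per_surgery_mean)))
        for _ in range(n_notes):
            day = int(rng.integers(0, 31)) if rng.random() < 0.05 else int(rng.integers(1, 31))
            role = (
                str(rng.choice(["physician", "resident", "surgery_assistant", "nurse"]))
                if rng.random() < 0.9
                else "other"
            )
            notes.append(
                ClinicalNote(
                    note_id=f"N{note_counter:06d}",
                    patient_id=pid,
                    surgery_id=sid,
                    note_date=surgery_date + dt.timedelta(days=day),
                    author_role=role,
                    text=_make_note_text(
                        rng, status, day, lexicon, keyword_rates,
                        config.negation_rate, config.language,
                    ),
                )
            )
            note_counter += 1

    return CohortTable(
        surgeries=surgeries,
        admissions=admissions,
        reoperations=reoperations,
        radiology=radiology,
        medications=medications,
        notes=notes,
        labels=labels,
    )


def subset_cohort(cohort: CohortTable, surgery_ids: Sequence[str]) -> CohortTable:
    """Restrict a cohort to the given surgeries (and their patients)."""
    wanted = set(surgery_ids)
    surgeries = [s for s in cohort.surgeries if s.surgery_id in wanted]
    patients = {s.patient_id for s in surgeries}
    return CohortTable(
        surgeries=surgeries,
        admissions=[a for a in cohort.admissions if a.patient_id in patients],
        reoperations=[r for r in cohort.reoperations if r.patient_id in patients],
        radiology=[r for r in cohort.radiology if r.patient_id in patients],
        medications=[m for m in cohort.medications if m.patient_id in patients],
        notes=[n for n in cohort.notes if n.surgery_id in wanted],
        labels=(
            [l for l in cohort.labels if l.surgery_id in wanted]
            if cohort.labels is not None
            else None
        ),
    )


def sample_development_cohort(
    n_high_probability: int = 250,
    seed: int = 0,
    language: str = "sv",
    keyword_rates: Optional[Mapping] = None,
) -> CohortTable:
    """A development cohort of structured-stage high-probability surgeries.

    Mirrors the study design: the structured algorithm is applied to a
    stream of surgeries and a sample of high-probability records (default
    250) forms the development cohort.  Generation proceeds in chunks
    until enough high-probability surgeries have accumulated.
    """
    from .structured import run_structured  # local import avoids a cycle

    collected: list[CohortTable] = []
    n_found = 0
    chunk = 0
    while n_found < n_high_probability and chunk < 50:
        cfg = GeneratorConfig(
            n_surgeries=max(50, int(1.2 * (n_high_probability - n_found) / 0.43)),
            seed=(seed * 1000 + chunk) % (2**31 - 1),
            id_prefix=f"D{chunk}-",
            language=language,
            keyword_rates=keyword_rates,
        )
        cohort = generate_cohort(cfg)
        hp_ids = [r.surgery_id for r in run_structured(cohort) if r.high_probability]
        hp_ids = hp_ids[: n_high_probability - n_found]
        collected.append(subset_cohort(cohort, hp_ids))
        n_found += len(hp_ids)
        chunk += 1
    merged = CohortTable(
        surgeries=[s for c in collected for s in c.surgeries],
        admissions=[a for c in collected for a in c.admissions],
        reoperations=[r for c in collected for r in c.reoperations],
        radiology=[r for c in collected for r in c.radiology],
        medications=[m for c in collected for m in c.medications],
        notes=[n for c in collected for n in c.notes],
        labels=[l for c in collected for l in c.labels],
    )
    return merged
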