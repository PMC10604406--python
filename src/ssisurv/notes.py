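"""Clinical-notes NLP: lexicon matching, negation, and keyword features.

Turns the free text of post-operative notes into per-surgery keyword
feature vectors in three representations:

* **raw** — the number of non-negated mentions per keyword;
* **discretized** — four bins: no occurrences, below the training
  interquartile range, within it, above it;
* **binary** — presence/absence of the keyword.

Only notes written by the surveilled roles (physicians, residents,
surgery assistants, nurses) within post-operative days 1–30 contribute.
Matching is lexicon-driven: each keyword carries explicit surface-form
variants (standing in for lemmatized/inflected spellings), optionally a
proximity requirement (nonspecific terms such as *fluid* only count
within five tokens of a body-location anchor), and an antibiotic-name
flag.  Negated mentions ("no signs of infection") are removed by a
NegEx-style trigger-and-scope pass before counting.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import ClinicalNote, CohortTable, SurgeryRecord, SURVEILLED_ROLES

#: Post-operative day window for notes under surveillance (inclusive).
NOTE_DAY_WINDOW = (1, 30)
#: Token distance allowed between a proximity keyword and its location anchor.
PROXIMITY_WINDOW = 5
#: Tokens a negation trigger's scope extends over.
NEGATION_SCOPE = 5

REPRESENTATIONS = ("raw", "discretized", "binary")
#: Bin codes of the discretized representation, in increasing count order.
BINS = ("none", "below", "within", "above")

_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)


class LexiconError(ValueError):
    """The lexicon violates its contract (duplicate variants, bad entry)."""


@dataclass(frozen=True)
class LexiconEntry:
    canonical_keyword: str
    variants: tuple[str, ...]
    requires_proximity: bool = False
    location_terms: tuple[str, ...] = ()
    is_antibiotic_name: bool = False

    def __post_init__(self) -> None:
        if not self.variants:
            raise LexiconError(f"{self.canonical_keyword}: variants must be non-empty")
        if self.requires_proximity != bool(self.location_terms):
            raise LexiconError(
                f"{self.canonical_keyword}: location_terms must be given "
                "exactly when requires_proximity is set"
            )


@dataclass(frozen=True)
class Lexicon:
    entries: tuple[LexiconEntry, ...]
    language: str = "sv"

    def __post_init__(self) -> None:
        seen: dict[tuple[str, ...], str] = {}
        for e in self.entries:
            for v in e.variants:
                key = tuple(tokenize(v))
                if key in seen and seen[key] != e.canonical_keyword:
                    raise LexiconError(
                        f"variant {v!r} maps to both {seen[key]!r} "
                        f"and {e.canonical_keyword!r}"
                    )
                seen[key] = e.canonical_keyword

    @property
    def keywords(self) -> tuple[str, ...]:
        return tuple(e.canonical_keyword for e in self.entries)

    def entry(self, canonical: str) -> LexiconEntry:
        for e in self.entries:
            if e.canonical_keyword == canonical:
                return e
        raise KeyError(canonical)


@dataclass(frozen=True)
class NegationTriggers:
    pre: tuple[str, ...]
    post: tuple[str, ...]
    terminators: tuple[str, ...]


@dataclass(frozen=True)
class KeywordMatch:
    canonical_keyword: str
    note_id: str
    token_position: int
    negated: bool = False
    day_post_surgery: int = 0
    is_antibiotic_name: bool = False


@dataclass(frozen=True)
class FeatureVector:
    """Per-surgery keyword features in one representation."""

    surgery_id: str
    representation: str
    values: Mapping[str, object]

    def __post_init__(self) -> None:
        if self.representation not in REPRESENTATIONS:
            raise ValueError(f"unknown representation {self.representation!r}")


@dataclass(frozen=True)
class DiscretizerModel:
    """Per-keyword Q1/Q3 bounds of positive training counts."""

    bounds: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for kw, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"{kw}: lower bound {lo} exceeds upper bound {hi}")


# ---------------------------------------------------------------------
# Default resources
# ---------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(resources.files("ssisurv").joinpath("data", name))  # type: ignore[arg-type]


def load_lexicon(path) -> Lexicon:
    """Read a lexicon from YAML or delimited text.

    CSV columns: canonical_keyword, variants ('|'-separated),
    requires_proximity, location_terms ('|'-separated), is_antibiotic_name.
    """
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        entries = tuple(
            LexiconEntry(
                canonical_keyword=e["canonical_keyword"],
                variants=tuple(e["variants"]),
                requires_proximity=bool(e.get("requires_proximity", False)),
                location_terms=tuple(e.get("location_terms", ())),
                is_antibiotic_name=bool(e.get("is_antibiotic_name", False)),
            )
            for e in raw["entries"]
        )
        return Lexicon(entries=entries, language=raw.get("language", "sv"))
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        entries = tuple(
            LexiconEntry(
                canonical_keyword=row["canonical_keyword"],
                variants=tuple(v for v in row["variants"].split("|") if v),
                requires_proximity=row.get("requires_proximity", "").lower() == "true",
                location_terms=tuple(
                    t for t in row.get("location_terms", "").split("|") if t
                ),
                is_antibiotic_name=row.get("is_antibiotic_name", "").lower() == "true",
            )
            for row in reader
        )
    return Lexicon(entries=entries)


def default_lexicon() -> Lexicon:
    """The shipped deep-SSI lexicon (Swedish variants, English canonicals)."""
    return load_lexicon(_data_path("default_lexicon.yaml"))


def load_triggers(path) -> NegationTriggers:
    """Read a trigger file: one `tag<TAB>phrase` per line (pre/post/term)."""
    pre, post, term = [], [], []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tag, _, phrase = line.partition("\t")
            {"pre": pre, "post": post, "term": term}[tag].append(phrase.strip())
    return NegationTriggers(pre=tuple(pre), post=tuple(post), terminators=tuple(term))


def default_triggers() -> NegationTriggers:
    return load_triggers(_data_path("negation_triggers.txt"))


def fixture_cohort_path() -> Path:
    """Directory of the bundled 12-surgery synthetic fixture cohort.

    Entirely generator output (seed 42); useful for fast examples and
    tests without generating anything.
    """
    return _data_path("synthetic_fixture_cohort")


# ---------------------------------------------------------------------
# Note filtering and tokenization
# ---------------------------------------------------------------------

def note_day(note: ClinicalNote, surgery: SurgeryRecord) -> int:
    return (note.note_date - surgery.surgery_date).days


def filter_notes(
    notes: Sequence[ClinicalNote], surgery: SurgeryRecord
) -> list[ClinicalNote]:
    """Notes by surveilled roles written within post-op days 1–30."""
    lo, hi = NOTE_DAY_WINDOW
    return [
        n
        for n in notes
        if n.author_role in SURVEILLED_ROLES and lo <= note_day(n, surgery) <= hi
    ]


def tokenize(text: str, normalizer=None) -> list[str]:
    """Lowercase word tokens, punctuation stripped, UTF-8 letters kept.

    *normalizer* is an optional ``str -> str`` hook applied per token —
    the plug-in point for an external lemmatizer/stemmer that maps
    inflected forms onto the surface forms listed in the lexicon.
    """
    tokens = [m.group(0).lower() for m in _TOKEN_RE.finditer(text)]
    if normalizer is not None:
        tokens = [normalizer(t) for t in tokens]
    return tokens


# ---------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------

def _phrase_spans(tokens: Sequence[str], phrases: Iterable[tuple[str, ...]]):
    """(start, end_inclusive) spans where any phrase matches contiguously."""
    spans = []
    by_first: dict[str, list[tuple[str, ...]]] = {}
    for p in phrases:
        if p:
            by_first.setdefault(p[0], []).append(p)
    for i, tok in enumerate(tokens):
        for p in by_first.get(tok, ()):
            if tuple(tokens[i : i + len(p)]) == p:
                spans.append((i, i + len(p) - 1))
    return spans


def match_keywords(tokens: Sequence[str], lexicon: Lexicon) -> list[KeywordMatch]:
    """One match per occurrence of any lexicon variant.

    Proximity-restricted entries only match when a location anchor lies
    within :data:`PROXIMITY_WINDOW` tokens of the keyword span, on either
    side.  Overlapping variants of the same canonical keyword at the same
    start position count once.
    """
    matches: list[KeywordMatch] = []
    for entry in lexicon.entries:
        variant_phrases = {tuple(tokenize(v)) for v in entry.variants}
        spans = sorted(set(_phrase_spans(tokens, variant_phrases)))
        # one count per (canonical, start position)
        seen_starts: set[int] = set()
        if entry.requires_proximity:
            loc_phrases = {tuple(tokenize(t)) for t in entry.location_terms}
            loc_spans = _phrase_spans(tokens, loc_phrases)
        for start, end in spans:
            if start in seen_starts:
                continue
            seen_starts.add(start)
            if entry.requires_proximity:
                ok = any(
                    (ls - end if ls > end else start - le) <= PROXIMITY_WINDOW
                    for ls, le in loc_spans
                )
                if not ok:
                    continue
            matches.append(
                KeywordMatch(
                    canonical_keyword=entry.canonical_keyword,
                    note_id="",
                    token_position=start,
                    is_antibiotic_name=entry.is_antibiotic_name,
                )
            )
    matches.sort(key=lambda m: (m.token_position, m.canonical_keyword))
    return matches


def apply_negation(
    tokens: Sequence[str],
    matches: Sequence[KeywordMatch],
    triggers: NegationTriggers,
) -> list[KeywordMatch]:
    """Mark matches inside a negation scope.

    A pre-trigger negates up to :data:`NEGATION_SCOPE` tokens following
    it; a post-trigger the tokens preceding it.  A scope ends early at a
    terminator conjunction ("but"/"men"), so "no fever but abscess
    present" leaves *abscess* affirmed.
    """
    term = set(triggers.terminators)
    negated_positions: set[int] = set()

    for start, end in _phrase_spans(tokens, [tuple(tokenize(t)) for t in triggers.pre]):
        for j in range(end + 1, min(end + 1 + NEGATION_SCOPE, len(tokens))):
            if tokens[j] in term:
                break
            negated_positions.add(j)
    for start, end in _phrase_spans(tokens, [tuple(tokenize(t)) for t in triggers.post]):
        for j in range(start - 1, max(start - 1 - NEGATION_SCOPE, -1), -1):
            if tokens[j] in term:
                break
            negated_positions.add(j)

    return [
        replace(m, negated=m.token_position in negated_positions) for m in matches
    ]


def extract_note_matches(
    note: ClinicalNote,
    surgery: SurgeryRecord,
    lexicon: Lexicon,
    triggers: Optional[NegationTriggers] = None,
    normalizer=None,
) -> list[KeywordMatch]:
    """Tokenize one note, match the lexicon, apply negation, stamp metadata."""
    triggers = triggers if triggers is not None else default_triggers()
    tokens = tokenize(note.text, normalizer)
    matches = apply_negation(tokens, match_keywords(tokens, lexicon), triggers)
    day = note_day(note, surgery)
    return [replace(m, note_id=note.note_id, day_post_surgery=day) for m in matches]


def extract_surgery_matches(
    cohort: CohortTable,
    surgery: SurgeryRecord,
    lexicon: Lexicon,
    triggers: Optional[NegationTriggers] = None,
) -> list[KeywordMatch]:
    """All matches over the surgery's filtered notes."""
    out: list[KeywordMatch] = []
    for note in filter_notes(cohort.notes_for(surgery.surgery_id), surgery):
        out.extend(extract_note_matches(note, surgery, lexicon, triggers))
    return out


# ---------------------------------------------------------------------
# Counting and representations
# ---------------------------------------------------------------------

def count_features(
    matches: Sequence[KeywordMatch], lexicon: Lexicon, surgery_id: str
) -> FeatureVector:
    """Raw per-keyword totals of non-negated matches across the notes."""
    counts = {kw: 0 for kw in lexicon.keywords}
    for m in matches:
        if not m.negated:
            counts[m.canonical_keyword] += 1
    return FeatureVector(surgery_id=surgery_id, representation="raw", values=counts)


def cohort_feature_vectors(
    cohort: CohortTable,
    lexicon: Optional[Lexicon] = None,
    triggers: Optional[NegationTriggers] = None,
    surgery_ids: Optional[Sequence[str]] = None,
):
    """Raw feature vectors (and the underlying matches) for a cohort.

    Returns ``(vectors, matches_by_surgery)``; restrict to a subset of
    surgeries with *surgery_ids*.
    """
    lexicon = lexicon if lexicon is not None else default_lexicon()
    triggers = triggers if triggers is not None else default_triggers()
    wanted = set(surgery_ids) if surgery_ids is not None else None
    vectors, matches_by_surgery = [], {}
    for surgery in cohort.surgeries:
        if wanted is not None and surgery.surgery_id not in wanted:
            continue
        matches = extract_surgery_matches(cohort, surgery, lexicon, triggers)
        matches_by_surgery[surgery.surgery_id] = matches
        vectors.append(count_features(matches, lexicon, surgery.surgery_id))
    return vectors, matches_by_surgery


def fit_discretizer(training_vectors: Sequence[FeatureVector]) -> DiscretizerModel:
    """Q1/Q3 of the positive (non-zero) training counts, per keyword.

    Quartiles use linear interpolation on the sorted positive counts.
    Zeros are excluded because the zero count has its own bin; a keyword
    never observed in training gets the degenerate bounds (1, 1).
    """
    if not training_vectors:
        raise ValueError("empty training set")
    _require_representation(training_vectors[0], "raw")
    keywords = list(training_vectors[0].values.keys())
    bounds: dict[str, tuple[float, float]] = {}
    for kw in keywords:
        positives = [v.values[kw] for v in training_vectors if v.values[kw] > 0]
        if positives:
            q1, q3 = np.percentile(positives, [25, 75], method="linear")
            bounds[kw] = (float(q1), float(q3))
        else:
            bounds[kw] = (1.0, 1.0)
    return DiscretizerModel(bounds=bounds)


def _require_representation(vector: FeatureVector, representation: str) -> None:
    if vector.representation != representation:
        raise ValueError(
            f"expected {representation} representation, got {vector.representation}"
        )


def discretize(vector: FeatureVector, model: DiscretizerModel) -> FeatureVector:
    """Map raw counts into the four bins none/below/within/above."""
    _require_representation(vector, "raw")
    values: dict[str, str] = {}
    for kw, count in vector.values.items():
        lo, hi = model.bounds[kw]
        if count == 0:
            values[kw] = "none"
        elif count < lo:
            values[kw] = "below"
        elif count <= hi:
            values[kw] = "within"
        else:
            values[kw] = "above"
    return FeatureVector(
        surgery_id=vector.surgery_id, representation="discretized", values=values
    )


def binarize(vector: FeatureVector) -> FeatureVector:
    """Presence/absence of each keyword."""
    _require_representation(vector, "raw")
    return FeatureVector(
        surgery_id=vector.surgery_id,
        representation="binary",
        values={kw: int(c > 0) for kw, c in vector.values.items()},
    )


def vectors_to_frame(vectors: Sequence[FeatureVector]) -> pd.DataFrame:
    """Wide table: one row per surgery, one column per canonical keyword."""
    if not vectors:
        return pd.DataFrame()
    frame = pd.DataFrame([dict(v.values) for v in vectors])
    frame.insert(0, "surgery_id", [v.surgery_id for v in vectors])
    frame.attrs["representation"] = vectors[0].representation
    return frame
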