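"""NLP-stage classifiers for the high-probability surgeries.

The NLP stage is sequential: it only ever sees surgeries the structured
algorithm already flagged as high probability, and can only remove them
from manual review, never add.  Because a missed deep SSI is lost for
good while a false positive is corrected at chart review, every
classifier here is operated at a sensitivity-prioritizing decision
threshold:

* a **miniature forest** of 10 small decision trees whose positive
  decision is the OR of the trees — equivalently a vote-fraction
  threshold of 0.1;
* a **random forest** of 500 trees whose conventional majority threshold
  of 0.5 is lowered (0.3 for raw/discretized counts, 0.35 for binary, or
  re-tuned against a development-cohort sensitivity floor of 0.95);
* a **rule engine** evaluating configurable OR/AND expressions over
  keyword presence.

Tree fitting is delegated to scikit-learn; vote aggregation,
thresholding, tuning, and the rule engine live here.
"""

from __future__ import annotations

import math
import pickle
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.tree import DecisionTreeClassifier

from .cohort import CohortTable
from .notes import (
    BINS,
    DiscretizerModel,
    FeatureVector,
    Lexicon,
    NegationTriggers,
    cohort_feature_vectors,
    binarize,
    discretize,
)
from .structured import StructuredResult, run_structured

#: Number of trees in the miniature decision-tree ensemble.
DT_ENSEMBLE_SIZE = 10
#: Its vote-fraction threshold (1 of 10 trees suffices).
DT_ENSEMBLE_THRESHOLD = 0.1
#: Random-forest size.
RF_N_TREES = 500
#: Conventional majority-vote threshold.
RF_DEFAULT_THRESHOLD = 0.5
#: Lowered thresholds selected for sensitivity, by representation.
RF_TUNED_THRESHOLDS = {"raw": 0.3, "discretized": 0.3, "binary": 0.35}
#: Development-cohort sensitivity floor used when re-tuning (strict >).
SENSITIVITY_FLOOR = 0.95
#: Default tuning grid.
DEFAULT_GRID = tuple(round(0.05 * i, 2) for i in range(1, 11))

#: Which feature representation each surveillance model uses.
MODEL_REPRESENTATIONS = {
    2: "raw",
    3: "discretized",
    4: "binary",
    5: "raw",
    6: "discretized",
    7: "binary",
}
MODEL_IDS = (1, 2, 3, 4, 5, 6, 7, 8)

_BIN_CODE = {b: i for i, b in enumerate(BINS)}


class TrainingError(ValueError):
    """Training preconditions violated (single class, bad stratum...)."""


class ThresholdError(ValueError):
    """No grid threshold attains the sensitivity floor."""

    def __init__(self, message: str, best_sensitivity: float):
        super().__init__(message)
        self.best_sensitivity = best_sensitivity


class RuleError(ValueError):
    """A rule expression fails to parse or names an unknown keyword."""


# ---------------------------------------------------------------------
# Feature matrices
# ---------------------------------------------------------------------

def design_matrix(
    vectors: Sequence[FeatureVector], feature_names: Sequence[str], representation: str
) -> np.ndarray:
    """Numeric matrix for tree models.

    Discretized bins are encoded ordinally (none<below<within<above →
    0..3): the bins are ordered in the underlying count, so numeric
    thresholds on the code express exactly the contiguous bin subsets a
    tree would otherwise select.
    """
    rows = []
    for v in vectors:
        if v.representation != representation:
            raise ValueError(
                f"vector {v.surgery_id} has representation {v.representation}, "
                f"expected {representation}"
            )
        if representation == "discretized":
            rows.append([_BIN_CODE[v.values[k]] for k in feature_names])
        else:
            rows.append([float(v.values[k]) for k in feature_names])
    return np.asarray(rows, dtype=float)


def transform_vectors(
    raw_vectors: Sequence[FeatureVector],
    representation: str,
    discretizer: Optional[DiscretizerModel] = None,
) -> list[FeatureVector]:
    if representation == "raw":
        return list(raw_vectors)
    if representation == "binary":
        return [binarize(v) for v in raw_vectors]
    if representation == "discretized":
        if discretizer is None:
            raise ValueError("discretized representation requires a fitted discretizer")
        return [discretize(v, discretizer) for v in raw_vectors]
    raise ValueError(f"unknown representation {representation!r}")


# ---------------------------------------------------------------------
# Ensembles
# ---------------------------------------------------------------------

@dataclass
class EnsembleModel:
    """A voting ensemble of decision trees over keyword features."""

    trees: list
    feature_subsets: list[np.ndarray]
    feature_names: tuple[str, ...]
    representation: str
    decision_threshold: float
    kind: str  # "dt_ensemble" | "random_forest"
    seed: Optional[int] = None

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def vote_matrix(self, vectors: Sequence[FeatureVector]) -> np.ndarray:
        """(n_trees, n_samples) boolean per-tree positive decisions."""
        X = design_matrix(vectors, self.feature_names, self.representation)
        votes = np.zeros((self.n_trees, len(vectors)), dtype=bool)
        for t, (tree, cols) in enumerate(zip(self.trees, self.feature_subsets)):
            votes[t] = tree.predict(X[:, cols]).astype(int) == 1
        return votes

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "EnsembleModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, EnsembleModel):
            raise TypeError(f"{path} does not contain an EnsembleModel")
        return model


def split_development(
    vectors: Sequence[FeatureVector],
    labels: Sequence[bool],
    fraction: float = 0.8,
    seed: int = 0,
):
    """Label-stratified train/test split of the development cohort.

    Returns ``(train_vectors, train_labels, test_vectors, test_labels)``;
    *fraction* is the training share.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must lie strictly in (0, 1), got {fraction}")
    y = np.asarray(labels, dtype=bool)
    if min(np.sum(y), np.sum(~y)) < 2:
        raise TrainingError("each label stratum needs at least 2 members to split")
    idx_train, idx_test = train_test_split(
        np.arange(len(vectors)), train_size=fraction, stratify=y, random_state=seed
    )
    return (
        [vectors[i] for i in idx_train],
        [bool(y[i]) for i in idx_train],
        [vectors[i] for i in idx_test],
        [bool(y[i]) for i in idx_test],
    )


def _check_two_classes(labels: Sequence[bool]) -> np.ndarray:
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise TrainingError("training labels contain a single class")
    return y


def train_dt_ensemble(
    vectors: Sequence[FeatureVector],
    labels: Sequence[bool],
    k: int = DT_ENSEMBLE_SIZE,
    seed: int = 0,
    max_depth: int = 3,
) -> EnsembleModel:
    """Fit the miniature forest of *k* small, deliberately varied trees.

    Diversification: each tree is grown on a bootstrap resample and a
    random feature subset of size ~sqrt(d), with shallow depth.  The
    ensemble's decision threshold is 0.1, i.e. one positive tree flags
    the surgery (the OR of the trees).
    """
    y = _check_two_classes(labels)
    feature_names = tuple(vectors[0].values.keys())
    representation = vectors[0].representation
    X = design_matrix(vectors, feature_names, representation)
    rng = np.random.default_rng(seed)
    n, d = X.shape
    subset_size = max(1, math.ceil(math.sqrt(d)))
    trees, subsets = [], []
    for _ in range(k):
        for _attempt in range(100):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y[idx])) == 2:
                break
        cols = np.sort(rng.choice(d, size=subset_size, replace=False))
        tree = DecisionTreeClassifier(
            max_depth=max_depth, random_state=int(rng.integers(0, 2**31 - 1))
        )
        tree.fit(X[idx][:, cols], y[idx])
        trees.append(tree)
        subsets.append(cols)
    return EnsembleModel(
        trees=trees,
        feature_subsets=subsets,
        feature_names=feature_names,
        representation=representation,
        decision_threshold=DT_ENSEMBLE_THRESHOLD,
        kind="dt_ensemble",
        seed=seed,
    )


def train_random_forest(
    vectors: Sequence[FeatureVector],
    labels: Sequence[bool],
    n_trees: int = RF_N_TREES,
    seed: int = 0,
) -> EnsembleModel:
    """Fit a standard bootstrap + random-feature-subset forest.

    The decision threshold starts at the conventional majority 0.5 and
    is lowered afterwards (see :func:`tune_threshold`).
    """
    y = _check_two_classes(labels)
    feature_names = tuple(vectors[0].values.keys())
    representation = vectors[0].representation
    X = design_matrix(vectors, feature_names, representation)
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    )
    forest.fit(X, y)
    all_cols = np.arange(X.shape[1])
    return EnsembleModel(
        trees=list(forest.estimators_),
        feature_subsets=[all_cols] * n_trees,
        feature_names=feature_names,
        representation=representation,
        decision_threshold=RF_DEFAULT_THRESHOLD,
        kind="random_forest",
        seed=seed,
    )


def predict_vote_fraction(
    model: EnsembleModel,
    vectors: Union[FeatureVector, Sequence[FeatureVector]],
):
    """Fraction of trees voting deep SSI, per surgery, in [0, 1]."""
    single = isinstance(vectors, FeatureVector)
    vecs = [vectors] if single else list(vectors)
    fractions = model.vote_matrix(vecs).mean(axis=0)
    return float(fractions[0]) if single else fractions


def classify_with_threshold(fraction, threshold: float):
    """Positive iff the vote fraction reaches the threshold (inclusive)."""
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    return np.asarray(fraction) >= threshold if np.ndim(fraction) else fraction >= threshold


def tune_threshold(
    model: EnsembleModel,
    vectors: Sequence[FeatureVector],
    labels: Sequence[bool],
    sensitivity_floor: float = SENSITIVITY_FLOOR,
    grid: Sequence[float] = DEFAULT_GRID,
) -> float:
    """Largest grid threshold with development sensitivity > floor.

    Largest = fewest false positives subject to the floor; the floor is
    strict.  Raises :class:`ThresholdError` (carrying the best attainable
    sensitivity) when no grid point qualifies.
    """
    if not grid:
        raise ValueError("empty threshold grid")
    if any(not 0 < t <= 1 for t in grid):
        raise ValueError("grid thresholds must lie in (0, 1]")
    y = np.asarray(labels, dtype=bool)
    if not y.any():
        raise TrainingError("tuning requires at least one positive label")
    fractions = predict_vote_fraction(model, vectors)
    best = 0.0
    for t in sorted(grid, reverse=True):
        sens = float(np.mean(fractions[y] >= t))
        best = max(best, sens)
        if sens > sensitivity_floor:
            return float(t)
    raise ThresholdError(
        f"no threshold in the grid attains sensitivity > {sensitivity_floor}; "
        f"best attainable is {best:.3f}",
        best_sensitivity=best,
    )


def train_for_model(
    model_id: int,
    raw_vectors: Sequence[FeatureVector],
    labels: Sequence[bool],
    seed: int = 0,
    discretizer: Optional[DiscretizerModel] = None,
    tune: bool = False,
    tune_vectors: Optional[Sequence[FeatureVector]] = None,
    tune_labels: Optional[Sequence[bool]] = None,
    sensitivity_floor: float = SENSITIVITY_FLOOR,
    grid: Sequence[float] = DEFAULT_GRID,
) -> EnsembleModel:
    """Fit the NLP classifier a given surveillance model calls for.

    Models 2–4 get the 10-tree OR-ensemble, models 5–7 the 500-tree
    forest.  Forest thresholds default to the selected 0.3/0.3/0.35
    (raw/discretized/binary); with ``tune=True`` the threshold is
    re-tuned on ``tune_vectors`` (default: the training data) against
    the sensitivity floor.
    """
    if model_id not in MODEL_REPRESENTATIONS:
        raise ValueError(f"model {model_id} has no trainable NLP classifier")
    representation = MODEL_REPRESENTATIONS[model_id]
    train_vecs = transform_vectors(raw_vectors, representation, discretizer)
    if model_id in (2, 3, 4):
        return train_dt_ensemble(train_vecs, labels, seed=seed)
    model = train_random_forest(train_vecs, labels, seed=seed)
    if tune:
        tv = (
            transform_vectors(tune_vectors, representation, discretizer)
            if tune_vectors is not None
            else train_vecs
        )
        tl = tune_labels if tune_labels is not None else labels
        model.decision_threshold = tune_threshold(
            model, tv, tl, sensitivity_floor=sensitivity_floor, grid=grid
        )
    else:
        model.decision_threshold = RF_TUNED_THRESHOLDS[representation]
    return model


# ---------------------------------------------------------------------
# Rule engine
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class RuleSpec:
    """Parsed OR/AND expression over keyword-presence atoms."""

    expression: tuple
    source: str

    def evaluate(self, vector: FeatureVector) -> bool:
        if vector.representation not in ("binary", "raw"):
            raise ValueError("rule evaluation needs a binary or raw feature vector")
        return _eval_expr(self.expression, vector.values)


def _eval_expr(node: tuple, values) -> bool:
    op = node[0]
    if op == "atom":
        return bool(values[node[1]])
    children = (_eval_expr(c, values) for c in node[1])
    return any(children) if op == "or" else all(children)


_RULE_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def parse_rule(text: str, lexicon: Lexicon) -> RuleSpec:
    """Parse an infix AND/OR expression with parentheses.

    Atoms are canonical keywords (multi-word names allowed, written as-is:
    ``abscess OR anastomotic leakage``).  Unknown keywords raise
    :class:`RuleError` at parse time.
    """
    tokens = _RULE_TOKEN_RE.findall(text)
    if not tokens:
        raise RuleError("empty rule expression")
    known = {k.lower(): k for k in lexicon.keywords}
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def parse_or():
        nonlocal pos
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            pos += 1
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else ("or", tuple(terms))

    def parse_and():
        nonlocal pos
        factors = [parse_factor()]
        while peek() is not None and peek().lower() == "and":
            pos += 1
            factors.append(parse_factor())
        return factors[0] if len(factors) == 1 else ("and", tuple(factors))

    def parse_factor():
        nonlocal pos
        tok = peek()
        if tok is None:
            raise RuleError(f"unexpected end of rule in {text!r}")
        if tok == "(":
            pos += 1
            inner = parse_or()
            if peek() != ")":
                raise RuleError(f"unbalanced parentheses in {text!r}")
            pos += 1
            return inner
        # atom: greedy run of words that are not operators/parens
        words = []
        while peek() is not None and peek() not in ("(", ")") and peek().lower() not in ("and", "or"):
            words.append(tokens[pos])
            pos += 1
        if not words:
            raise RuleError(f"expected a keyword at token {tok!r} in {text!r}")
        name = " ".join(words).lower()
        if name not in known:
            raise RuleError(f"rule references unknown keyword {name!r}")
        return ("atom", known[name])

    expr = parse_or()
    if pos != len(tokens):
        raise RuleError(f"trailing tokens in rule {text!r}")
    return RuleSpec(expression=expr, source=text)


def rule_based_classify(vector: FeatureVector, rules: RuleSpec) -> bool:
    """Probable deep SSI iff the OR/AND expression holds for the vector."""
    return rules.evaluate(vector)


# ---------------------------------------------------------------------
# End-to-end semi-automated surveillance
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class SurveillanceResult:
    surgery_id: str
    structured: StructuredResult
    vote_fraction: Optional[float]
    nlp_positive: Optional[bool]
    final_review_flag: bool
    model_id: int


def run_semiautomated(
    cohort: CohortTable,
    model_id: int,
    nlp_model: Optional[EnsembleModel] = None,
    rules: Optional[RuleSpec] = None,
    lexicon: Optional[Lexicon] = None,
    triggers: Optional[NegationTriggers] = None,
    discretizer: Optional[DiscretizerModel] = None,
    structured_results: Optional[Sequence[StructuredResult]] = None,
    raw_vectors: Optional[Sequence[FeatureVector]] = None,
) -> list[SurveillanceResult]:
    """Run one surveillance model over a cohort.

    Model 1 flags exactly the structured high-probability surgeries.
    Models 2–7 apply the given ensemble (threshold included in the
    model), model 8 the rule engine, in each case only to the
    high-probability surgeries: a low-probability surgery is never
    flagged.  Precomputed ``structured_results`` / ``raw_vectors`` may
    be passed to avoid recomputation across models.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id}; expected one of {MODEL_IDS}")
    structured = (
        list(structured_results) if structured_results is not None else run_structured(cohort)
    )
    by_id = {r.surgery_id: r for r in structured}
    if model_id == 1:
        return [
            SurveillanceResult(
                surgery_id=r.surgery_id,
                structured=r,
                vote_fraction=None,
                nlp_positive=None,
                final_review_flag=r.high_probability,
                model_id=1,
            )
            for r in structured
        ]

    high_prob_ids = [r.surgery_id for r in structured if r.high_probability]
    if raw_vectors is None:
        raw_vectors, _ = cohort_feature_vectors(
            cohort, lexicon, triggers, surgery_ids=high_prob_ids
        )
    vec_by_id = {v.surgery_id: v for v in raw_vectors}
    missing = [sid for sid in high_prob_ids if sid not in vec_by_id]
    if missing:
        raise ValueError(f"no feature vectors for high-probability surgeries {missing}")
    hp_raw = [vec_by_id[sid] for sid in high_prob_ids]

    fractions: dict[str, float] = {}
    positive: dict[str, bool] = {}
    if model_id == 8:
        if rules is None:
            raise ValueError("model 8 requires a rule specification")
        for sid, vec in zip(high_prob_ids, hp_raw):
            positive[sid] = rule_based_classify(binarize(vec), rules)
    else:
        if nlp_model is None:
            raise ValueError(f"model {model_id} requires a fitted ensemble")
        representation = MODEL_REPRESENTATIONS[model_id]
        if nlp_model.representation != representation:
            raise ValueError(
                f"model {model_id} uses {representation} features but the "
                f"ensemble was fitted on {nlp_model.representation}"
            )
        vecs = transform_vectors(hp_raw, representation, discretizer)
        if high_prob_ids:
            frac = predict_vote_fraction(nlp_model, vecs)
            for sid, f in zip(high_prob_ids, np.atleast_1d(frac)):
                fractions[sid] = float(f)
                positive[sid] = bool(f >= nlp_model.decision_threshold)

    out = []
    for r in structured:
        sid = r.surgery_id
        out.append(
            SurveillanceResult(
                surgery_id=sid,
                structured=r,
                vote_fraction=fractions.get(sid),
                nlp_positive=positive.get(sid),
                final_review_flag=r.high_probability and positive.get(sid, False),
                model_id=model_id,
            )
        )
    return out
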