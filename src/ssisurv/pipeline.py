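"""End-to-end orchestration: featurize → train → classify → evaluate.

Glue shared by the command-line interface, the acceptance script and the
test suite.  The NLP stage is fitted once on a development cohort of
high-probability records and then applied, model by model, to a cohort
under surveillance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .classifiers import (
    DEFAULT_GRID,
    MODEL_REPRESENTATIONS,
    SENSITIVITY_FLOOR,
    EnsembleModel,
    RuleSpec,
    SurveillanceResult,
    run_semiautomated,
    train_for_model,
)
from .cohort import CohortTable
from .evaluation import PerformanceRow, build_confusion, compute_metrics
from .notes import (
    DiscretizerModel,
    Lexicon,
    NegationTriggers,
    cohort_feature_vectors,
    default_lexicon,
    default_triggers,
    fit_discretizer,
)
from .structured import run_structured


@dataclass
class FittedSurveillance:
    """Everything the NLP-augmented models need at prediction time."""

    lexicon: Lexicon
    triggers: NegationTriggers
    discretizer: Optional[DiscretizerModel] = None
    models: dict[int, EnsembleModel] = field(default_factory=dict)
    rules: Optional[RuleSpec] = None


def fit_nlp_stage(
    dev_cohort: CohortTable,
    model_ids: Sequence[int],
    lexicon: Optional[Lexicon] = None,
    triggers: Optional[NegationTriggers] = None,
    rules: Optional[RuleSpec] = None,
    seed: int = 0,
    tune: bool = False,
    sensitivity_floor: float = SENSITIVITY_FLOOR,
    grid: Sequence[float] = DEFAULT_GRID,
) -> FittedSurveillance:
    """Fit discretizer and classifiers on a labelled development cohort."""
    lexicon = lexicon if lexicon is not None else default_lexicon()
    triggers = triggers if triggers is not None else default_triggers()
    fitted = FittedSurveillance(lexicon=lexicon, triggers=triggers, rules=rules)
    trainable = [m for m in model_ids if m in MODEL_REPRESENTATIONS]
    if not trainable:
        return fitted
    if dev_cohort.labels is None:
        raise ValueError("development cohort carries no reference labels")
    vectors, _ = cohort_feature_vectors(dev_cohort, lexicon, triggers)
    by_id = dev_cohort.labels_by_surgery()
    labels = [by_id[v.surgery_id].deep_ssi for v in vectors]
    fitted.discretizer = fit_discretizer(vectors)
    for m in trainable:
        fitted.models[m] = train_for_model(
            m,
            vectors,
            labels,
            seed=seed,
            discretizer=fitted.discretizer,
            tune=tune,
            sensitivity_floor=sensitivity_floor,
            grid=grid,
        )
    return fitted


def apply_models(
    cohort: CohortTable,
    model_ids: Sequence[int],
    fitted: FittedSurveillance,
) -> dict[int, list[SurveillanceResult]]:
    """Run each requested surveillance model over the cohort."""
    structured = run_structured(cohort)
    hp_ids = [r.surgery_id for r in structured if r.high_probability]
    raw_vectors = None
    if any(m != 1 for m in model_ids):
        raw_vectors, _ = cohort_feature_vectors(
            cohort, fitted.lexicon, fitted.triggers, surgery_ids=hp_ids
        )
    out: dict[int, list[SurveillanceResult]] = {}
    for m in model_ids:
        out[m] = run_semiautomated(
            cohort,
            m,
            nlp_model=fitted.models.get(m),
            rules=fitted.rules,
            lexicon=fitted.lexicon,
            triggers=fitted.triggers,
            discretizer=fitted.discretizer,
            structured_results=structured,
            raw_vectors=raw_vectors if m != 1 else None,
        )
    return out


def evaluate_models(
    cohort: CohortTable,
    results_by_model: Mapping[int, Sequence[SurveillanceResult]],
    ci_method: str = "clopper-pearson",
) -> dict[int, PerformanceRow]:
    if cohort.labels is None:
        raise ValueError("evaluation requires reference labels")
    return {
        m: compute_metrics(
            build_confusion(results, cohort.labels), model_id=m, ci_method=ci_method
        )
        for m, results in results_by_model.items()
    }
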