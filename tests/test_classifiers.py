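"""Ensembles, thresholds, the rule engine, and sequential surveillance."""

import numpy as np
import pytest

from ssisurv.notes import FeatureVector
from ssisurv.classifiers import (
    RuleError,
    ThresholdError,
    TrainingError,
    classify_with_threshold,
    parse_rule,
    predict_vote_fraction,
    rule_based_classify,
    run_semiautomated,
    split_development,
    train_dt_ensemble,
    train_for_model,
    train_random_forest,
    tune_threshold,
)
from ssisurv.notes import Lexicon, LexiconEntry
from ssisurv.pipeline import apply_models, fit_nlp_stage
from ssisurv.structured import run_structured
from ssisurv.synthetic import (
    GeneratorConfig,
    generate_cohort,
    sample_development_cohort,
    subset_cohort,
    well_separated_keyword_rates,
)

KEYWORDS = ("abscess", "drainage", "infection", "fluid")


def _vec(values, sid="s", representation="raw"):
    return FeatureVector(surgery_id=sid, representation=representation, values=values)


def _random_vectors(rng, n, p_signal=0.5):
    """Random raw vectors; label = presence of 'abscess' (perfect separator)."""
    vecs, labels = [], []
    for i in range(n):
        pos = rng.random() < p_signal
        values = {
            "abscess": int(pos) * rng.integers(1, 4),
            "drainage": int(rng.integers(0, 3)),
            "infection": int(rng.integers(0, 4)),
            "fluid": int(rng.integers(0, 2)),
        }
        vecs.append(_vec(values, f"s{i}"))
        labels.append(bool(pos))
    return vecs, labels


# ---------------------------------------------------------------- splitting
def test_split_80_20_stratified():
    rng = np.random.default_rng(0)
    vecs, labels = _random_vectors(rng, 250, p_signal=0.4)
    tr_v, tr_y, te_v, te_y = split_development(vecs, labels, fraction=0.8, seed=1)
    assert len(tr_v) == 200 and len(te_v) == 50
    # stratification keeps the prevalence within a seat of the overall one
    assert abs(np.mean(tr_y) - np.mean(labels)) < 0.01
    ids = {v.surgery_id for v in tr_v} | {v.surgery_id for v in te_v}
    assert len(ids) == 250  # disjoint and exhaustive


def test_split_reproducible_under_seed():
    rng = np.random.default_rng(3)
    vecs, labels = _random_vectors(rng, 60)
    a = split_development(vecs, labels, seed=9)
    b = split_development(vecs, labels, seed=9)
    assert [v.surgery_id for v in a[0]] == [v.surgery_id for v in b[0]]


@pytest.mark.parametrize("fraction", [0.0, 1.0, 1.5])
def test_split_fraction_bounds(fraction):
    rng = np.random.default_rng(0)
    vecs, labels = _random_vectors(rng, 20)
    with pytest.raises(ValueError):
        split_development(vecs, labels, fraction=fraction)


def test_split_small_stratum_errors():
    vecs = [_vec({"abscess": i}, f"s{i}") for i in range(10)]
    labels = [True] + [False] * 9
    with pytest.raises(TrainingError):
        split_development(vecs, labels)


# ---------------------------------------------------------------- DT ensemble
def test_dt_ensemble_shape_and_threshold():
    rng = np.random.default_rng(1)
    vecs, labels = _random_vectors(rng, 80)
    model = train_dt_ensemble(vecs, labels, k=10, seed=0)
    assert model.n_trees == 10
    assert model.decision_threshold == 0.1


def test_dt_ensemble_perfect_separator_has_full_training_sensitivity():
    rng = np.random.default_rng(2)
    vecs, labels = _random_vectors(rng, 100)
    model = train_dt_ensemble(vecs, labels, seed=0)
    fractions = predict_vote_fraction(model, vecs)
    decisions = fractions >= model.decision_threshold
    positives = np.asarray(labels)
    assert decisions[positives].all()  # sensitivity 1.0 on training data


def test_dt_ensemble_single_class_errors():
    vecs = [_vec({"abscess": i % 3}, f"s{i}") for i in range(10)]
    with pytest.raises(TrainingError):
        train_dt_ensemble(vecs, [False] * 10)


def test_dt_ensemble_decision_equals_or_of_trees():
    """Vote fraction ≥ 0.1 with 10 trees is exactly the OR of the votes."""
    rng = np.random.default_rng(4)
    train, labels = _random_vectors(rng, 120)
    model = train_dt_ensemble(train, labels, seed=7)
    probe, _ = _random_vectors(rng, 1000)
    votes = model.vote_matrix(probe)           # (10, 1000)
    ensemble = predict_vote_fraction(model, probe) >= model.decision_threshold
    assert np.array_equal(ensemble, votes.any(axis=0))


# ---------------------------------------------------------------- forest
def test_random_forest_size_default_threshold_and_determinism():
    rng = np.random.default_rng(5)
    vecs, labels = _random_vectors(rng, 100)
    model = train_random_forest(vecs, labels, n_trees=500, seed=2)
    assert model.n_trees == 500
    assert model.decision_threshold == 0.5
    probe, _ = _random_vectors(rng, 40)
    again = train_random_forest(vecs, labels, n_trees=500, seed=2)
    assert np.array_equal(
        predict_vote_fraction(model, probe), predict_vote_fraction(again, probe)
    )


def test_vote_fraction_counts_trees():
    rng = np.random.default_rng(6)
    vecs, labels = _random_vectors(rng, 60)
    model = train_dt_ensemble(vecs, labels, seed=1)
    probe = vecs[0]
    per_tree = model.vote_matrix([probe])[:, 0]
    assert predict_vote_fraction(model, probe) == per_tree.sum() / model.n_trees


def test_vote_fraction_representation_mismatch_errors():
    rng = np.random.default_rng(6)
    vecs, labels = _random_vectors(rng, 60)
    model = train_dt_ensemble(vecs, labels, seed=1)
    binary_probe = _vec({k: 1 for k in KEYWORDS}, representation="binary")
    with pytest.raises(ValueError, match="representation"):
        predict_vote_fraction(model, binary_probe)


# ---------------------------------------------------------------- thresholds
@pytest.mark.parametrize(
    "fraction, threshold, expected",
    [(0.32, 0.3, True), (0.32, 0.35, False), (0.5, 0.5, True), (0.1, 0.1, True)],
)
def test_classify_with_threshold_inclusive(fraction, threshold, expected):
    assert classify_with_threshold(fraction, threshold) is expected


def test_tune_threshold_selects_largest_qualifying(monkeypatch):
    import ssisurv.classifiers as clf

    fractions = np.array([0.9, 0.6, 0.45, 0.4, 0.31, 0.2])
    labels = [True, True, True, True, True, False]
    monkeypatch.setattr(clf, "predict_vote_fraction", lambda m, v: fractions)
    # sensitivity by threshold: 0.5→0.8, 0.45→0.8... 0.4→... grid walk:
    # t=0.30: all five positives ≥0.31 → sens 1.0 (first > 0.95 going down)
    t = clf.tune_threshold(object(), [None] * 6, labels, grid=(0.3, 0.35, 0.4, 0.45, 0.5))
    assert t == 0.3


def test_tune_threshold_perfect_classifier_takes_top_of_grid(monkeypatch):
    import ssisurv.classifiers as clf

    monkeypatch.setattr(clf, "predict_vote_fraction",
                        lambda m, v: np.array([1.0, 1.0, 0.0]))
    labels = [True, True, False]
    assert clf.tune_threshold(object(), [None] * 3, labels) == 0.5


def test_tune_threshold_unattainable_floor_reports_best(monkeypatch):
    import ssisurv.classifiers as clf

    monkeypatch.setattr(clf, "predict_vote_fraction",
                        lambda m, v: np.array([0.9, 0.0]))
    with pytest.raises(ThresholdError) as err:
        clf.tune_threshold(object(), [None] * 2, [True, True],
                           sensitivity_floor=1.01)
    assert err.value.best_sensitivity == pytest.approx(0.5)


# ---------------------------------------------------------------- rule engine
@pytest.fixture(scope="module")
def rule_lexicon():
    return Lexicon(
        entries=(
            LexiconEntry("abscess", ("abscess",)),
            LexiconEntry("leakage", ("leakage",)),
            LexiconEntry("antibiotics", ("antibiotics",)),
            LexiconEntry("drained", ("drained",)),
        )
    )


def test_rule_and(rule_lexicon):
    rule = parse_rule("abscess AND drained", rule_lexicon)
    both = _vec({"abscess": 1, "drained": 1, "leakage": 0, "antibiotics": 0},
                representation="binary")
    one = _vec({"abscess": 1, "drained": 0, "leakage": 0, "antibiotics": 0},
               representation="binary")
    assert rule_based_classify(both, rule) is True
    assert rule_based_classify(one, rule) is False


def test_rule_truth_table(rule_lexicon):
    """(abscess OR leakage) AND antibiotics over all 8 presence combinations."""
    rule = parse_rule("(abscess OR leakage) AND antibiotics", rule_lexicon)
    for a in (0, 1):
        for l in (0, 1):
            for ab in (0, 1):
                v = _vec({"abscess": a, "leakage": l, "antibiotics": ab, "drained": 0},
                         representation="binary")
                assert rule_based_classify(v, rule) == bool((a or l) and ab)


def test_rule_unknown_keyword_errors(rule_lexicon):
    with pytest.raises(RuleError, match="unknown keyword"):
        parse_rule("abscess AND sepsis", rule_lexicon)


def test_rule_unbalanced_parens(rule_lexicon):
    with pytest.raises(RuleError):
        parse_rule("(abscess OR leakage", rule_lexicon)


# ---------------------------------------------------------------- pipeline
@pytest.fixture(scope="module")
def small_world():
    """Small dev + validation cohorts with well-separated note signal."""
    rates = well_separated_keyword_rates()
    dev = sample_development_cohort(n_high_probability=120, seed=21,
                                    keyword_rates=rates)
    cfg = GeneratorConfig(n_surgeries=80, seed=22, keyword_rates=rates,
                          id_prefix="V")
    return dev, generate_cohort(cfg)


def test_low_probability_surgeries_never_flagged(small_world):
    dev, val = small_world
    fitted = fit_nlp_stage(dev, [2, 3, 4, 8], seed=0,
                           rules=parse_rule("abscess", fitted_lexicon()))
    results = apply_models(val, [1, 2, 3, 4, 8], fitted)
    for mid, rows in results.items():
        for r in rows:
            if not r.structured.high_probability:
                assert r.final_review_flag is False


def fitted_lexicon():
    from ssisurv.notes import default_lexicon

    return default_lexicon()


def test_model1_flags_exactly_high_probability(small_world):
    _, val = small_world
    structured = {r.surgery_id: r.high_probability for r in run_structured(val)}
    for r in run_semiautomated(val, 1):
        assert r.final_review_flag == structured[r.surgery_id]
        assert r.vote_fraction is None and r.nlp_positive is None


def test_sequential_dominance(small_world):
    dev, val = small_world
    fitted = fit_nlp_stage(dev, [3, 4], seed=0)
    results = apply_models(val, [1, 3, 4], fitted)
    flagged1 = {r.surgery_id for r in results[1] if r.final_review_flag}
    for mid in (3, 4):
        flagged = {r.surgery_id for r in results[mid] if r.final_review_flag}
        assert flagged <= flagged1


def test_threshold_monotonicity(small_world):
    """Lower thresholds: sensitivity never drops, specificity never rises."""
    dev, val = small_world
    fitted = fit_nlp_stage(dev, [6], seed=0)
    model = fitted.models[6]
    results = apply_models(val, [6], fitted)[6]
    labels = val.labels_by_surgery()
    fractions = {r.surgery_id: (r.vote_fraction if r.vote_fraction is not None else -1.0)
                 for r in results}
    hp = {r.surgery_id for r in results if r.structured.high_probability}
    prev_sens, prev_spec = None, None
    for t in sorted([0.05 * i for i in range(1, 11)]):
        flagged = {sid for sid in hp if fractions[sid] >= t}
        pos = [sid for sid in fractions if labels[sid].deep_ssi]
        neg = [sid for sid in fractions if not labels[sid].deep_ssi]
        sens = sum(sid in flagged for sid in pos) / len(pos)
        spec = sum(sid not in flagged for sid in neg) / len(neg)
        if prev_sens is not None:
            assert sens <= prev_sens + 1e-12
            assert spec >= prev_spec - 1e-12
        prev_sens, prev_spec = sens, spec


def test_model8_without_matches_not_flagged(rule_lexicon):
    cfg = GeneratorConfig(n_surgeries=30, seed=33, notes_per_surgery_mean=1.0)
    cfg.keyword_rates = {}  # no keyword emissions at all
    cohort = generate_cohort(cfg)
    rule = parse_rule("abscess", rule_lexicon)
    from ssisurv.notes import default_lexicon

    results = run_semiautomated(cohort, 8, rules=rule, lexicon=default_lexicon())
    assert not any(r.final_review_flag for r in results)


def test_unknown_model_id_errors(small_world):
    _, val = small_world
    with pytest.raises(ValueError, match="model_id"):
        run_semiautomated(val, 9)


def test_train_for_model_forest_thresholds():
    rng = np.random.default_rng(8)
    vecs, labels = _random_vectors(rng, 80)
    m5 = train_for_model(5, vecs, labels, seed=0)
    m7 = train_for_model(7, vecs, labels, seed=0)
    assert m5.decision_threshold == 0.3 and m5.representation == "raw"
    assert m7.decision_threshold == 0.35 and m7.representation == "binary"


def test_ensemble_model_save_load_round_trip(tmp_path):
    rng = np.random.default_rng(9)
    vecs, labels = _random_vectors(rng, 60)
    model = train_dt_ensemble(vecs, labels, seed=4)
    path = tmp_path / "ensemble.pkl"
    model.save(path)
    from ssisurv.classifiers import EnsembleModel

    loaded = EnsembleModel.load(path)
    probe, _ = _random_vectors(rng, 30)
    assert np.array_equal(predict_vote_fraction(model, probe),
                          predict_vote_fraction(loaded, probe))
    assert loaded.decision_threshold == model.decision_threshold
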