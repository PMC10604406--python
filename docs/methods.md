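# Methods

This note documents the modelling choices behind `ssisurv`: the
surveillance procedure and its conventions, the NLP configuration, the
classifiers and their thresholds, the evaluation statistics, and what
the synthetic-cohort generator does and does not emulate.

## Surveillance procedure and day-window conventions

All timing is whole-day arithmetic relative to the index surgery date
(day 0).  Follow-up for the structured components is 45 days; windows
are inclusive of their endpoints.  Conventions that the wording
"within follow-up" leaves open were fixed as follows:

* **Index admission** = the admission whose `[admit, discharge]`
  interval contains the surgery date; with several candidates, the
  earliest admission.  An admission with no discharge date is treated
  as extending through follow-up, so its length-of-stay criterion
  fires.  If no admission contains the surgery date the component
  still evaluates its readmission and mortality criteria (with a
  logged warning), using the surgery's department as the index
  department.
* **Readmission** = a new admission to the index department with an
  admit date strictly after the index discharge, in days 1–45.
* **Re-surgery** counts from day 1 ("after the index surgery");
  **radiology** (CT orders, not performed scans) from day 0.
* **Antibiotics**: calendar days in [2, 45] with ≥ 1 administration
  whose ATC code has prefix `J01`; the component fires on a run of ≥ 3
  consecutive such days.  Days 0–1 never contribute, which keeps
  routine perioperative prophylaxis from triggering the component.
* High probability ⇔ ≥ 2 of the 4 components.

Adding events can only switch components off→on, never on→off, and all
components are invariant to event order; both properties are tested.

## Notes NLP

**Filtering.**  Only notes by physicians, residents, surgery assistants
and nurses, written in post-operative days 1–30 (inclusive), are
analysed.  Other roles are retained in the data model and excluded at
filter time, so raw data is never silently dropped.

**Lexicon.**  Keyword normalization uses explicit per-entry surface-form
variant lists instead of a language-specific lemmatizer/POS pipeline: a
variant table is portable across languages, auditable, and exactly
testable; a custom lexicon file (YAML or CSV) can carry the output of
any external normalizer.  The shipped default covers the deep-SSI
keyword set (abscess, anastomotic leakage, drainage, drained, leakage,
antibiotics, subfebrile, fluid, intestinal content, serous, echo,
infection) plus nine antibiotic substances with common brand names,
with Swedish and English surface forms.  Nonspecific terms (fluid,
serous, echo, leakage) carry a **proximity requirement**: they only
count within 5 tokens of a body-location anchor (abdomen, wound,
pelvis, anastomosis, …).  Which keywords carry the anchor requirement
is a lexicon property and fully overridable.

**Matching.**  Tokenization lowercases and strips punctuation while
preserving Unicode letters (å/ä/ö survive).  Multi-word variants match
as contiguous token sequences; variants of the same keyword starting at
the same position count once.

**Negation.**  A trigger-and-scope pass in the NegEx style: a
pre-trigger ("no", "without", "ingen", "utan", …) negates up to 5
following tokens, a post-trigger ("unlikely", "osannolikt", …) the 5
preceding tokens, and a scope ends early at a conjunction
("but"/"men"/"dock"), so "no fever but abscess present" leaves
*abscess* affirmed.  The 5-token scope and the trigger lists are the
conventional NegEx defaults, shipped as a plain-text file (tagged
pre/post/term) and overridable.  Negated mentions are never counted;
disabling negation can only increase counts (tested property).

**Representations.**  Raw counts sum non-negated matches over a
surgery's filtered notes (additive by construction).  The discretizer
maps a count to `none` (0), `below` (< Q1), `within` ([Q1, Q3]) or
`above` (> Q3), where Q1/Q3 are quartiles of the **positive** training
counts with linear interpolation.  Zeros are excluded from the IQR
because the zero count owns a bin; including them would collapse Q1 to
0 for sparse keywords and merge `below` into `within`.  A keyword never
observed in training gets degenerate bounds (1, 1), so any later
occurrence lands in `within`/`above` sensibly.  Binary presence is
`count > 0`.

## Classifiers and thresholds

The NLP stage is strictly sequential: it sees only surgeries the
structured stage flagged, and can only unflag them.  Every flagged set
of models 2–8 is therefore a subset of model 1's, so workload reduction
can only rise and sensitivity only fall relative to model 1 — the
dominance property the acceptance suite checks on random cohorts.

* **Miniature forest (models 2–4).**  Ten shallow trees (default max
  depth 3), each grown on a bootstrap resample with a random feature
  subset of size ⌈√d⌉ — the diversification that makes ten "slightly
  different" trees out of one training set; the mechanism is
  configurable.  The ensemble decision threshold is 0.1, which with 10
  trees is exactly the OR of the trees (tested as an identity).
* **Random forest (models 5–7).**  scikit-learn's
  `RandomForestClassifier` with 500 trees.  The vote fraction is the
  share of trees voting positive (computed from the individual trees,
  not averaged probabilities).  Default decision thresholds: 0.3 for
  raw and discretized counts, 0.35 for binary.  `tune_threshold`
  re-derives them: the largest grid value (default grid 0.05…0.50 in
  steps of 0.05) whose development sensitivity strictly exceeds 0.95 —
  largest because, subject to the sensitivity floor, a higher threshold
  flags fewer false positives.  If no grid point qualifies the tuner
  raises, reporting the best attainable sensitivity.
* **Threshold comparisons are inclusive** (`fraction ≥ threshold`):
  the 0.1 ensemble threshold must make 1-in-10 votes positive, which
  forces inclusivity; 0.5 at the conventional majority threshold is
  likewise positive.
* **Discretized features in trees** are encoded ordinally
  (none < below < within < above → 0–3).  Because the bins are ordered
  in the underlying count, numeric splits on the code express exactly
  the contiguous bin subsets a set-membership split would select, while
  keeping the sklearn tree machinery unmodified.
* **Rule engine (model 8).**  Infix OR/AND expressions with parentheses
  over keyword-presence atoms (multi-word keyword names written as-is).
  Rules are configuration: no default rule set ships, since a rule
  reflecting a local case definition is a per-site clinical decision.
* The development split is label-stratified 80/20; all training
  randomness flows from one seed parameter.

## Evaluation

Sensitivity, specificity, PPV and NPV are binomial proportions; 95% CIs
are exact Clopper–Pearson by default (small samples, boundary
proportions like 40/41 — asymptotic intervals would be anti-conservative
there), with Wilson as the configurable alternative.  A metric with a
zero denominator is reported as *undefined*, never silently 0.
Workload reduction is the flagged-complement share,
`(total − flagged)/total × 100`, so WR plus the flagged percentage is
exactly 100 before rounding.  Reports round to one decimal; internal
values keep full precision.  Keyword distributions are tabulated per
(keyword, day bin, deep-SSI group) with default bins 1–7 / 8–14 / 15–30
days, the long-format table behind the heat map.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes,
not clinical reality:

* Labels are Bernoulli(prevalence).  Each structured component fires
  with an SSI-conditional rate, realized through concrete events
  (a ≥ 14-day stay, a same-department readmission, an in-hospital
  death, a same-specialty reoperation, a CT order, a ≥ 3-day J01 run)
  plus decoys that must *not* fire components (other-department
  readmissions, other-specialty reoperations, MRI/ultrasound orders,
  isolated antibiotic doses with ≥ 2-day gaps, day-0 prophylaxis).
* Notes are keyword/filler token sequences, not prose.  Keyword
  mentions are Poisson per note with (keyword, SSI status, day bin)
  rates; deep-SSI emission concentrates in days 15–30.
  Proximity-requiring keywords are emitted with a location anchor; a
  configurable share of mentions (default 0.15) is negated by
  prefixing a trigger, with enough filler between mentions that one
  mention's trigger cannot reach the next mention's scope.  The default
  token mode is Swedish, keeping UTF-8 handling honest.
* **Validation-like preset**: 225 surgeries, prevalence 41/225 ≈ 18.2%.
  Per-component rates 0.80 (SSI-positive) / 0.275 (SSI-negative) were
  derived analytically from the 2-of-4 rule: P(≥2 of 4) = 0.973 and
  0.304 respectively, giving an expected flagged fraction of
  0.182·0.973 + 0.818·0.304 ≈ 0.426 ≈ 96/225 and an expected 97% of
  SSI-positive surgeries flagged.  A Monte-Carlo test confirms the
  calibration.
* **Parameter-recovery conditions**: `well_separated_keyword_rates`
  raises positive-class emissions and nearly zeroes negative-class
  emissions, the premise under which the NLP stage must recover the
  signal.  The end-to-end check trains on a 250-record development
  cohort and evaluates on a held-out cohort of 2 000 surgeries with a
  mean of 6 notes per surgery: the larger held-out size keeps the
  binomial noise of a ~40-positive draw from dominating the property
  under test (the NLP stage retaining sensitivity while strictly
  improving workload reduction), and the higher note density keeps the
  premise — that flagged positives *have* signal-bearing notes —
  satisfied for all but a negligible fraction of surgeries.

What passing these tests shows: the pipeline's stages compose
correctly, the thresholds enforce the sensitivity priority, and the
classifiers recover a separable notes signal.  What it does not show:
performance on real clinical language (synonyms, misspellings,
indirect descriptions, section structure), on real event-rate
correlations between components, or on any particular hospital's
documentation habits.

## Known limitations

* The lexicon is the reconstructable core keyword set, not a full
  expert-curated list; real deployments should extend it.
* No spelling correction, no section segmentation, no embedding-based
  text models — by design, to keep the NLP stage auditable.
* The rule engine ships without a default rule set (site-specific).
* Multi-admission patients with several admissions overlapping the
  surgery date resolve to the earliest; other conventions are
  plausible and would need a one-line change.
* The generator draws components independently given SSI status; real
  components are correlated (a reoperation usually implies a CT and
  antibiotics), which the dominance and recovery tests do not exercise.
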