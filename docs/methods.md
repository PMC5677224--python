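# Methods

This note documents the models and procedures `contextfuse` implements, the
semantic choices made where the design was genuinely open, and what the
synthetic-data tests do and do not establish.

## Data model

A **low-level context** (LLC) is one observation of one user over a half-open
interval `[start, end)` in epoch seconds: an `Activity`, `Location`,
`Emotion` or `Food` label, or a clinical reading (`BloodGlucose` mg/dL,
`BloodPressure` systolic/diastolic mmHg, `WaterIntake` accumulated mL/day)
that may arrive raw and be labeled by the package.  Clinical readings are
point events (zero-length intervals).  Calendar-day grouping uses a
configurable UTC offset (`engine.tz_offset_hours`, default 0).

A **high-level context** (HLC) candidate carries a partial assertion map over
the object properties `hasActivity`, `hasLocation`, `hasEmotion`, `hasFood`,
`hasBloodGlucose`, `hasBloodPressure` — one label per property — plus the
union span of its source records.  Domains: PA (physical activity), N
(nutrition), C (clinical health state).

All terminological content is configuration (`data/default_config.yaml`):
vocabularies, the food-group and major-nutrient maps, labeling thresholds,
class definitions, rules and engine parameters.  The packaged food list
contains the ten fixed Fats items plus a replaceable USDA-style default for
the remaining 47 of the 57 items; users with their own taxonomy edit the
YAML, not the code.

## Clinical labeling

**Blood glucose** uses six bands with deliberately non-contiguous printed
bounds; the uncovered values (exactly 70, 108–120, 180–215, 280–314 mg/dL)
map to the sentinel `UnspecifiedBG`.  Sentinel readings are logged and
excluded from clinical fusion rather than being rounded into a neighboring
band: the band edges are clinical content, and inventing boundaries would be
a silent change of that content.

**Blood pressure** bounds are printed as combined systolic/diastolic pairs
without a rule for discordant components.  The package categorizes each
component independently against ordered bands and returns the more severe
label (severity `LowBP < NormalBP < PreHypertension < HypertensionStageI <
HypertensionStageII`) — a standard clinical convention, implemented as a
swappable policy.  Two details of the default band tables:

* the low band (`< 90/60`) is numerically inside the normal band (`≤ 120/80`);
  bands are checked most-severe-first with `LowBP` before `NormalBP`, so the
  narrower band wins;
* the printed hypertensive upper bounds (`< 159/99`, `< 139/89`) leave
  one-unit gaps below the next band's lower bound.  The default tables carry
  only the lower bounds for those bands, closing each gap downward.  This
  honors every printed lower bound and keeps labeling monotone in each
  component (raising a reading can never lower the severity), which strict
  upper bounds would violate at the gap edges.  `UnspecifiedBP` remains in
  the API for user-supplied band sets with real gaps.

**Water intake** splits strictly at the normal daily volume (2000 mL):
below → `Dehydration`, exactly → `NormalIntake`, above → `OverHydration`.
An optional `tolerance_ml` widens the normal band; the default is 0 because
the source threshold is stated as a single approximate value and a strict
reading is the least surprising default.

## Synchronization

Two records of one user are concurrent when their intervals overlap or their
start times differ by at most the window length (default 15 s, configurable);
groups are the transitive closure of that relation.  The start-proximity arm
exists because point events have empty intervals and can never overlap
anything.  With records sorted by start, a single pass tracking the group's
latest start and furthest end computes the closure exactly; the test suite
checks it against an all-pairs union-find oracle.

Per concurrency group, three instantiators emit at most one candidate each:

* **PA** requires an Activity record (the PA classes are activity-driven);
  location and emotion attach when present, and classification decides
  whether they suffice.
* **N** requires a Food record *and* an `Eating` activity; location/emotion
  attach when present.
* **C** requires at least one labeled (non-sentinel) glucose or pressure
  record.  Water intake is carried as metadata and, by default, never
  triggers a clinical candidate on its own (it appears in the clinical
  vocabulary but not among the clinical object properties).

When a group holds two records of one category, the one with the longest
overlap with the group span wins; ties go to the earliest start.  Records
referenced by no candidate are returned in an `unconsumed` report — nothing
is dropped silently.

## Vertical fusion (classification)

A class definition is a set of restrictions per property:

* *existential* — a witness set; **mandatory** witnesses must each be hit by
  the asserted value, and if any **non-mandatory** witness sets are declared,
  at least one must be hit ("any-of");
* *universal* — an allowed set; every asserted value of a constrained
  property must lie in it.

Description-logic reasoning is open-world; the effective behavior of
asserting per-instance "only" closure axioms and running a DL reasoner is
reproduced here by *automatic closure*: an instance's assertion map is taken
as its complete value set, so universal restrictions are checked directly.
This makes classification a finite, deterministic check — the package is
deliberately not a general OWL reasoner (no TBox subsumption, no tableau).

Classes within a domain are pairwise disjoint; a double match raises an
error indicting the definition set.  No match yields `Unidentified` with a
reason code: the alphabetically first property that is a mandatory witness
of some candidate class yet absent from the instance (`missing:hasLocation`
being the typical dropout signature), or `assertion_mismatch` when all
mandatory properties were present but carried out-of-set values.

Shipped definitions:

* **N** (anchored to the published Fats definition): `hasActivity some/only
  Eating`, `hasLocation some/only (Home | Office | Restaurant)`, `hasEmotion
  only` the five emotions, and a per-class `hasFood` set.  The Fats food set
  is the fixed ten-item list; Carbohydrates and Protein derive from the
  food-group map by major nutrient (Grain/Fruits/Vegetable/Snacks →
  Carbohydrates; Meat/SeaFood/Eggs/Legumes/Nuts/MilkAndDairyProducts →
  Protein) with the Fats items overriding their group, so the three sets
  partition the 57 items.
* **C**: the four health states encode a severity ladder.  Each state's
  existential witnesses are the labels *at* its severity (glucose or
  pressure, any-of), and its universal sets allow labels at or below it;
  an instance carrying both readings therefore classifies to the more severe
  state without any special-case code.  Band-to-state assignment:
  Normal ← NormalBG/NormalBP; Moderate ← BorderlineBG, LowBG,
  PreHypertension, LowBP; HighRisk ← HighBG, HypertensionStageI;
  VeryHighRisk ← DangerouslyHighBG, DangerouslyLowBG, HypertensionStageII.
  The hypo bands sit in Moderate as a default judgment call.
* **PA**: the full published axioms of the eight activity classes are not
  machine-readable, so the defaults key each class on its activity set, with
  a mandatory location for location-specific classes (OfficeWork =
  sitting@Office, Exercising = walking/running/cycling/stretching at
  Loc_Gym/Outdoors, …).  `Inactivity` covers `Act_LyingDown` and `Eating`
  anywhere: an eating bundle is also a (sedentary) physical-activity context,
  and this keeps clean streams fully classifiable.  These definitions are
  explicit, swappable approximations.

**Notification** is communicated-on-change: a classified HLC is delivered
only when the user's inferred class in that domain differs from the previous
one, so `communicated ≤ recognized` always.

## Horizontal fusion (behavioral rules)

Rules are conjunctive queries evaluated in a rolling window of
`engine.week_seconds` (default 7 days) ending at the evaluation time, in
four phases: nested-loop matching of the antecedent atoms; grouping per user
(plus optional `group_by` variables such as the calendar day); aggregation
(`sum`, `count`, `count_distinct`) with filter comparisons; projection.
This mirrors the collection-then-aggregation semantics of SQWRL-style
queries; the atom set is intentionally limited to what the six packaged
rules need (no negation-as-failure, no general rule language).

Interpretation choices for the packaged rules, where the printed forms are
ambiguous:

* "in a week" is the rolling 7-day window; the day count `d` is the number
  of **distinct local calendar days** carrying a matched context.  (Reading
  `d` as a per-context duration would make the printed `equal(d, 7)`
  unsatisfiable.)
* Rules 1–3 compare the **summed** exercising hours over the window
  ("less than two hours in a week" is a weekly total); Rules 4–5 filter the
  **per-session** duration (1–3 h) before counting days/sessions.
* Rule 1's gym-location atom is read as "the Exercising context occurred at
  `Loc_Gym`"; Rules 2–3 require the context's activity to be walking /
  running respectively.
* Rule 5 groups qualifying sessions per (user, day) and selects days with
  exactly two; Rule 6 groups `Eating` activities per (user, day) — the
  printed grouping variable is unbound, and (user, day) is the reading that
  makes "meals per day" well defined — and selects days with frequency > 2.
* `sum` and `count_distinct` are engine aggregation builtins beyond the
  printed makeSet/groupBy/size set; they express the weekly-total and
  distinct-day readings directly.

A user may satisfy several rules at once (e.g. daily twice-a-day training
satisfies both the daily and the twice-daily rule); results are reported
as-is, ordered by (rule id, user, bindings).

## Synthetic cohort generator

Each user follows one archetype day plan built from non-overlapping
episodes: sleep 00:00–06:45, office blocks 09:00–12:00 and 13:30–16:30,
breakfast and dinner at home, morning glucose + pressure self-measurements
10 s apart, an evening water-total reading, a 21:00–23:30 rest block, and an
archetype gym plan:

| archetype | gym plan (at Loc_Gym) | intended rule |
|---|---|---|
| sedentary | one 1.5 h walk per week | 1 (total < 2 h, < 7 days) |
| lightly_active | 20 min walk daily (2.33 h/wk) | 2 |
| moderately_active | 35 min run daily (4.08 h/wk) | 3 |
| very_active | 2 h run daily | 4 |
| extremely_active | 2 × 1.25 h runs daily | 4 and 5 |
| irregular_eater | none; 4 meals/day | 6 |

Emotions and food items are drawn uniformly per episode/meal; daily clinical
labels are drawn from categorical distributions (mostly unremarkable, with
occasional extremes) and the raw values uniformly **inside the target
label's band** — never in a printed gap — so that a clean stream is fully
classifiable.  Ground truth comes from construction: HLC truth from the
episode plan (each meal contributes both its nutrition class and an
`Inactivity` PA context; the clinical pair contributes the severity-max
health state via a flat lookup), behavioral truth from a direct tally over
the gym/meal plan, independent of the rule engine under test.

Missingness is modeled as independent per-record dropout at a given rate,
seeded separately.  Dropping a location unclassifies location-mandatory
candidates (`missing:hasLocation`); dropping a trigger record (activity,
food, both clinical readings) removes the candidate entirely, which the
evaluation reports as a *missing candidate* rather than an unidentified one.

What the generator does **not** emulate: realistic activity-recognizer error
(labels are never wrong, only absent), inter-episode transitions, schedule
jitter beyond a few seconds, correlated or burst dropout, per-user clinical
trajectories, or the distributions of any real cohort.  Consequently the
clean-stream closure result (100% accuracy) validates the *pipeline's
internal consistency* — that synchronization, classification and rule
evaluation jointly invert the generative schedule — not field accuracy on
real sensor data, and the dropout sweep characterizes sensitivity to missing
records only.

## Evaluation

The confusion matrix covers the fifteen classes in a fixed legend order plus
an `Unidentified` predicted column; instances pair with truth by (user,
domain, interval overlap), greedily in time order — exact on clean streams.
Accuracy, misclassified and unidentified fractions sum to 1 over the matched
pairs.  Precision/recall/F are the standard per-class definitions with
undefined values reported as missing, not zero; macro averages skip them.
The historical variants `paper_precision` (correct inferences divided by the
number of defined classes — a count ratio that can exceed 1) and
`paper_recall` (correct over dataset size) are reported as secondary
scalars only.

## Problem sizes and numerics

The shipped test and acceptance runs use a 20-user × 7-day cohort
(≈ 3,700 records, ≈ 1,460 HLCs), 10,000 random instances for the classifier
oracle, 100 random fact bases (≤ 200 facts) for the rule-engine oracle, and
exhaustive integer sweeps for the labelers — sizes chosen so the whole suite
runs in seconds on one CPU while every code path is exercised.  Floating
point is used plainly: durations are exact binary fractions of an hour in
the fixtures, rule thresholds are compared with strict inequalities as
printed, and RDF time literals carry millisecond precision.  Determinism:
every random draw flows from an explicit seed (cohorts spawn per-user
sub-seeds from the master seed), grouping and classification are
order-independent, and rule output is canonically sorted.

## Known limitations

* The PA and C class definitions beyond the nutrition domain are reasoned
  defaults, not published axioms; swap them in config for other taxonomies.
* 47 of the 57 food items are a stand-in list; the group and nutrient maps
  are data and clearly marked replaceable.
* The rule engine supports exactly the builtin vocabulary of the six
  packaged rules.
* Closure-based classification cannot represent genuinely open-world
  reasoning (e.g. inferring from the *absence* of an assertion that a value
  may still exist); within this pipeline that is by design.
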