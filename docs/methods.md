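# Methods

This note documents the model and procedure implemented by `caawd`, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical and design choices made where the design was
genuinely open.

## Behavior model

The unit of analysis is the *behavior instance*: one occurrence of an
activity of daily living (ADL), described by start time, a discretized
time bin, the household object used, the room, the ordered sub-activities
observed while the activity was open, the duration in whole minutes, and
a wellness class (Normal/Abnormal).  Instances are produced by a stateful
sweep over the binary sensor stream:

* a main-sensor ON opens an instance (duration *undetermined* until the
  OFF arrives); sub-sensor ONs are recognized only while their parent is
  open, and repeats of the same sub-activity collapse to one mention;
* the main OFF closes the instance; the activity interval is closed-open
  `[ON, OFF)` and the duration is `OFF − ON` in minutes, calendar-aware
  across midnight;
* overlapping *different* activities are legal and close independently;
  a sub event with no open parent, or an OFF with no ON, is logged and
  skipped; an unknown sensor is an error;
* instances still open at stream end are emitted with undetermined
  duration and excluded from mining (they cannot form complete items).

Timestamps are minute-resolution local times without timezone; all
printed artifacts use ISO 8601.

## Itemization

For rule mining an instance becomes a transaction of `attribute=value`
items: one item each for time bin, object, location, activity and
duration bin, plus one item per distinct sub-activity.  Two
discretizations matter:

* **time bins** (default 60 min, midnight-anchored; any divisor of 1440
  works): coarse enough that a routine performed at slightly different
  clock times lands in one bin, fine enough that nocturnal deviations
  land elsewhere;
* **duration bins** (default 15 min): rules over exact minutes would
  never reach minimum support.

The per-activity tuple (one instance carrying the ordered sub-activity
list, expanded into items at mining time) avoids double-counting an
activity's support; a row-per-sub-activity export dialect exists for
interoperability.

## Rule mining

Class association rules `A → c` are mined with a hand-written FP-growth
whose tree nodes carry per-class counts, so one pass yields rules for
both classes.  A rule is kept iff its joint relative support
`|A ∪ c| / |D|` ≥ θ′ (default 0.01) and its confidence
`|A ∪ c| / |A|` ≥ 0.5.  Anti-monotone pruning operates on the
antecedent's total support, an upper bound on every class-joint support.
Antecedent length is capped at 7 (the instance schema's attribute
arity).  The deliberately low θ′ keeps low-frequency routine fragments;
pruning is the classifier's job, not the miner's.

## Lazy classification

At query time the rule base is projected onto the test itemset.  Among
the projected rules:

* **wrong** rules — majority class of their matching training instances
  differs from their consequent (ties are not wrong) — are pruned;
* **used** rules are the non-wrong rules that are the top-ranked
  applicable rule for at least one training instance; the rest are
  **sparse**.  Sparse rules are consulted only when no used rule applies
  (a `best-rank` policy that lets a sparse rule outrank a used one is
  available behind a flag, since the two readings cannot be
  distinguished from the method's description).

Ranking is by information gain of the antecedent-match event about the
class, computed against the full training data and cached per rule.
Entropy is Shannon entropy in bits with `0·log 0 = 0`; IG is clamped at
0 and an antecedent matching no training instance has IG 0 by
definition (with a warning).  Ties break deterministically by higher
confidence, higher support, longer antecedent, then lexicographic
antecedent.  An empty projection (or one whose rules are all wrong)
falls back to Abnormal — total deviation from every learned routine
fragment is itself the anomaly signal — configurable via
`fallback_class`.

## Caregiver context validation

A caregiver context assigns each activity up to three inclusive ranges:
daily frequency, duration (minutes) and start time (24 h clock, no
midnight wrap by default).  Abnormal-classified instances are
re-examined with AND logic; absent ranges pass vacuously (otherwise an
activity with no prescribed clock window could never be contextually
normal).  Frequency is counted per calendar day over *all* observed
instances of the activity — Normal-classified ones advance the counter
too — and is incremented before the check, so the instance being
validated counts itself.  Only the abnormal→normal correction is
implemented; demoting a Normal call on contextual grounds is noted as an
open direction, not guessed.  Range units are minutes and clock times
throughout (the formal definition mentions seconds once, but every
printed range is in minutes or hours; minutes are used consistently).

Confirmed abnormalities emit alarm records naming the activity, room,
time, and each violated attribute with observed value and expected
range; a rule-based flag with no range violation is described as a
departure from the learned routine pattern.

## Synthetic smart home

The generator emulates a four-room, single-resident home with ten ADLs
(sleeping, toileting ×4–6/day, showering, three meals, snack, TV,
grooming, leaving), each tied to a main sensor and, for meals and
toileting, a fixed-order burst of sub-sensors.  Every draw (start time,
duration, daily frequency) is uniform inside an explicit per-activity
window, seeded; the windows are chosen to be commensurate with the
default bins so routine behavior is stable under itemization.  Sleeping
crosses midnight (23:05–23:25 start, 8 h ± duration).

Anomaly injection perturbs scheduled episodes four ways: duration
shifts, start-time shifts, frequency shifts (extra occurrences) and
missing activities (a day with zero events for the activity).  Each
perturbed episode is verified to leave its routine envelope (otherwise
the spec is rejected), and, when a caregiver context and an expected
contextual verdict are declared, the verdict is re-derived with the
validator's own semantics and checked before the stream is returned.

Two packaged benchmarks define the study conditions:

* **Cohort benchmark** (10 subjects × 14 days, 20% anomalies): the
  anomaly rate is applied per activity (stratified), so every ADL
  carries the same incidence; each anomaly type is a *canonical
  deviation* — sleeping ~2.5 h longer than usual, toileting between
  02:00 and 04:00, a near-zero walk, a tripled TV session — whose
  target window fits inside a single off-routine itemization bin.
  Uniform (non-stratified) selection and diffuse magnitude windows were
  considered and rejected as benchmark design: they model labeling
  noise rather than characteristic behavioral deviations, and they make
  per-activity anomaly incidence swing wildly between simulated
  subjects.
* **Contextual benchmark** (2000 instances: 1000 normal, 1000 abnormal,
  of which 500 contextually normal): a fixed 16-instance/day routine
  over 125 days.  Contextually-normal perturbations land inside every
  caregiver range (including the running-frequency check: the late-day
  toileting slot is the day's sixth occurrence, inside the 4–8 range),
  contextually-abnormal ones violate exactly one range outright.  The
  500/500 split is therefore structural — invariant to the seed — while
  individual magnitudes still vary with it.

What the generator does **not** emulate: sensor noise or dropout,
multi-resident interaction, physically grounded occupancy, seasonal or
weekly routine drift, and anomalies that are *ambiguous* in item space
(e.g. a duration drift of a few minutes).  Passing tests therefore show
that the stack recovers planted, characteristic deviations under clean
sensing; they do not certify performance on noisy real deployments.

## Evaluation protocol

Stratified seeded k-fold cross-validation (default k = 10; `k = |D|`
degenerates to leave-one-out), with mining and classification re-run
inside every fold.  Training folds are balanced to class parity by
seeded oversampling of the minority class; the default method
replicates each minority instance a whole number of times and fills the
remainder with a seeded draw without replacement, because uneven
duplication multiplicities (the plain with-replacement draw, also
available as `method="sample"`) distort the confidence and information
gain of mined rules.  Balancing never touches test folds, and no
synthetic instances are invented.  Abnormal is the positive class
(alarms fire on it); metrics with zero denominators are reported as
undefined rather than 0; weighted aggregates are instance-count-weighted
means.

## Parameter summary

| parameter | default | unit | why |
|---|---|---|---|
| time bin width | 60 | min | hour-scale routines; divisor of 1440 |
| duration bin width | 15 | min | support-reachable duration items |
| minimum support θ′ | 0.01 | relative | keep low-frequency routine fragments |
| minimum confidence | 0.5 | — | majority-consistent rules only |
| antecedent length cap | 7 | items | instance schema arity |
| fallback class | Abnormal | — | no-routine-match is the signal |
| CV folds | 10 | — | evaluation protocol |
| anomaly rate (cohort) | 0.2 | fraction | benchmark condition |

## Known limitations

* Information-gain ranking is computed on the *global* training data;
  rules that are pure within a projection but globally rare can be
  outranked by broad mixed rules when class composition is badly
  skewed — class balancing is what keeps this in check.
* The interval export dialect identifies sensors by (object, room), so
  homes with duplicate descriptors cannot round-trip losslessly.
* Missing-activity anomalies produce no behavior instance and are
  reported as day-level records, not rows, so instance-level metrics do
  not see them.
* The caregiver context is declarative input; no learning or drift
  adaptation is attempted.
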