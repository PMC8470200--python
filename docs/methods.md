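# Methods

## Conceptual model

`wearkg` models wearable data at two levels of abstraction.

**Observations** follow the SOSA core pattern: an observation node links a
feature of interest (one of `movement`, `sleep`, `heart`), an observed
property from a controlled vocabulary of 18 properties, a numeric result
with unit, and a half-open phenomenon-time interval `[start, end)`
(instantaneous per-minute samples get `[t, t + 1 min)`). Observation
*types* form a three-branch hierarchy whose membership conditions are OWL
equivalence axioms combining a feature nominal with a finite property set:

| class | condition |
|---|---|
| MovementObservation | feature = movement, property ∈ MovementProperty |
| MovementIntensity | above, property ∈ {fair/high/light_activity, sedentary} |
| WalkingFeature | above, property ∈ {distance, elevation, floors, steps} |
| SleepObservation | feature = sleep, property ∈ SleepProperty |
| AsleepCount / AsleepDuration / AwakeCount / AwakeDuration | above, the named property |
| HeartObservation | feature = heart, property ∈ {heart_rate, cardio, fat_burn, peak} |
| Cardio / FatBurn / HeartRate / Peak | above, the named property |

Because every axiom uses only nominals and one-property existentials over
a finite vocabulary, classification is implemented as forward evaluation
of these predicates closed under parents. This is semantically exact for
this hierarchy — a general DL reasoner would produce the same
entailments — and removes a heavyweight dependency. The core sleep
vocabulary is extended with `minutes_to_fall_asleep` and `efficiency` so
the sleep rules have typed inputs; both classify as `SleepObservation`
without a dedicated leaf class.

**Situations** follow the Descriptions-and-Situations pattern. A detected
problem is a `Situation` with at least one `View` (a `Description`) and at
least one interpreted `Observation`; the view defines one `Concept` per
distinct feature of interest among the interpreted observations, each
classifying the corresponding observed-property entity. The subproperty
entailments (`hasView ⊑ satisfies`, `interprets ⊑ isSettingFor`) are
materialised in the graph, and `validate_descriptive_context` checks all
of these structural conditions, reporting violations rather than raising.
A problem spanning a day interprets *all* contributing observations (not
one aggregate); a single-observation interpretation is a special case of
the same code path. Problems map to Web-Annotation records with views as
bodies and interpreted observations as targets, preserving the WADM
cardinalities (0+ bodies, 1+ targets).

Problem categories follow the three branches of the core vocabulary:
sleep problems (Insomnia, Restlessness, TooMuchSleep, LackOfSleep,
IncreasedNapping, NapCloseToBedtime, LowSleepQuality), heart problems
(StressOrPain, LowHeartRate) and activity problems (Inactivity,
LackOfMovement, LackOfExercise). The assignment is a config-level map and
can be overridden.

## Rule base

All comparisons are strict, and every threshold is per-subject
overridable; the defaults are:

| rule | condition | scope |
|---|---|---|
| Insomnia | time to fall asleep in a day > 1800 s | daily |
| Restlessness | sleep interruptions in a day > 10 | daily |
| TooMuchSleep | total sleep in a day > 480 min | daily |
| LackOfSleep | total sleep in a day < 300 min | daily |
| IncreasedNapping | asleep in naps > 100 min in a day | daily |
| NapCloseToBedtime | nap ends < 2 h before main sleep start | daily |
| LowSleepQuality | session efficiency < 85 | per session |
| LackOfExercise | steps in a day < 8000 | daily |
| StressOrPain | steps < 50 & HR > 90 for > 300 min | window |
| LowHeartRate | HR < 60 | per-minute run |
| Inactivity | steps < 1000 & HR < 80 for > 300 min | window |
| LackOfMovement | steps < 500 & HR < 100 for > 800 min | window |

Decisions taken where the design was genuinely open:

- **Day attribution.** Samples belong to the date of their timestamp; a
  sleep session belongs to the date of its *end* (the morning a night's
  sleep finishes). Missing minutes are absence, not zero: days without
  sleep sessions skip the sleep rules (missing data is non-adherence, not
  zero sleep) and days without step samples skip the step rule.
- **Nap designation.** The `is_main_sleep` flag wins when present;
  otherwise the day's longest session (tie → earliest start) is main
  sleep and all others are naps. A nap-count variant of IncreasedNapping
  is exposed in config with no default threshold.
- **NapCloseToBedtime across midnight.** The main sleep a nap precedes
  usually starts that evening but is attributed to the next morning's
  date. The rule therefore compares each nap's end with the start of the
  next main sleep chronologically after it, and the problem is attributed
  to the nap's own day.
- **One problem per rule per day.** LowSleepQuality is evaluated per
  session, but a day with several failing sessions yields one problem
  interpreting every failing session's efficiency observation, keeping the
  at-most-one-per-(rule, subject, day) invariant uniform across rules.
- **Composite window semantics.** A window is a maximal contiguous run of
  minutes each carrying an HR sample that satisfies the heart-rate
  comparison; minutes lacking an HR sample break runs. The step condition
  is *cumulative over the run* while the HR condition is per minute:
  per-minute step counts rarely approach 500, so a per-minute reading of
  the step thresholds would make them vacuous. Window durations are
  minutes. A run fires when its length strictly exceeds the duration
  threshold and its step total satisfies the step comparison; windows are
  maximal, hence disjoint, and each yields one problem.
- **Sleep masking for window rules.** By default, HR minutes inside a
  sleep session are excluded before window detection. Sustained low heart
  rate with zero steps is the normal physiology of sleep: without masking,
  every ordinary night (~460 min of HR ≈ 64 and no steps) would satisfy
  *Inactivity* (HR < 80 for > 300 min) and routinely *LowHeartRate*,
  drowning the waking-hour signal these rules are meant to capture. The
  masking happens in the pipeline before `find_hr_step_windows` /
  `find_low_hr_runs`, whose run semantics are unchanged; a config flag
  (`include_sleep_minutes`) restores the raw behaviour.
- **Fat-burn parenthetical.** The StressOrPain condition is HR > 90; the
  "fat burn zone" gloss is treated as commentary, not an extra condition.
- **Ordering.** Problems are emitted sorted by (extent start, type), and
  generated IRIs are deterministic hashes of (subject, type, extent
  start), so identical inputs yield byte-identical outputs.

The rule base is exported as a SHACL-SPARQL document (Turtle, one
`sh:SPARQLRule` with a `CONSTRUCT` body producing the DnS problem shape
per rule). Rules whose semantics exceed a single graph pattern — daily
aggregation, session grouping, maximal windows — carry an `rdfs:comment`
saying what the native engine evaluates; the native engine is
authoritative and the document is an interoperability artifact, not an
execution target.

## Synthetic data

The generator is parametric, with no claim of distributional fidelity to
any real cohort; it emulates the *structure* of wearable exports and the
conditions the rules consume. The default profile describes a compliant
subject: daily step totals ~N(12000, 1500²) distributed over waking
minutes with a mild mid-afternoon peak (multinomial draw, so totals are
exact and values are non-negative integers, zero during sleep); night
sleep with bedtime 23:00 ± 15 min, asleep ~N(420, 25²) min, sleep-onset
~N(12, 4²) min, Poisson(2) awakenings at ~3 min each; waking HR
~N(74, 3²) plus 0.2 bpm per step/min, sleeping HR ~N(64, 1.5²), clipped
to a resting floor of 61 bpm; 15 % of days have one 20–60 min afternoon
nap. Under the default thresholds this profile yields problem-free days
~96 % of the time — the residue being honest distribution tails (a
−2.7 σ step day falls under 8000; a +2.4 σ night exceeds 480 min). A
single integer seed drives all draws in a fixed order (sessions, then
steps, then HR, day by day), so output is byte-reproducible.

`inject_problem_episode` rewrites one day to provably satisfy a chosen
rule: session fields are adjusted (with efficiency recomputed and streams
kept consistent — extended sleep silences steps, shortened sleep frees
minutes as restless waking), naps are added or removed, and waking HR/step
windows are forced with run-breaking HR values just outside the window so
the injected run is maximal by construction. Every injection is
post-checked by running the detector on a three-day slice around the
target day and raises if the rule does not fire; days other than the
injected one are untouched.

What passing tests on this data do *not* show: robustness to device noise,
wear-time gaps, daylight-saving shifts or timezone travel, multi-device
fusion, or the distributional quirks of real patient cohorts. The rules
are deterministic condition checks, so synthetic coverage of their
boundaries is exhaustive in a way real data could not be — but that says
nothing about whether the thresholds are clinically right for a given
person, which is why they are per-subject configuration.

## Numerical and engineering choices

- Sleep efficiency, when absent from input, is `round(100 × asleep / in-bed)`
  with ties away from zero — the rules compare it against integer limits.
- Timestamps are ISO-8601 without timezone (one implicit local timezone);
  streams are sorted before validation and reject duplicate timestamps,
  negative values and (for steps) non-integers, reporting the row number.
- Run detection is vectorised (minute indices + boolean mask + diff-based
  run splitting; prefix sums for window step totals), so whole-range
  detection over months of minute data takes tens of milliseconds.
- Graph serialization to Turtle uses a canonical flat form (prefix header
  + sorted one-triple lines, no blank nodes), which is byte-stable and
  fast on minute-resolution graphs; JSON-LD uses the standard serializer
  and is intended for the (small) annotation exports.
- The benchmark harness cuts Task-2 dataset prefixes at whole-day
  boundaries (largest day prefix not exceeding the requested object
  count): a partially observed day could make a daily rule flicker as the
  rest of its sessions arrive, whereas day-aligned prefixes make
  generated-problem counts non-decreasing by construction. Wall-clock
  times are reported but never asserted.
- Problem sizes in the test suite are chosen to keep the default run
  fast: the injection-soundness sweep uses 3-day datasets (the smallest
  window in which a day has both neighbours), the window-oracle
  comparison 200 streams of ≤ 2000 minutes, the compliance check 30–100
  days.

## Known limitations

- Exercise sessions (fat-burn/cardio/peak minutes) are parsed and typed
  but no default rule consumes them.
- The NapCloseToBedtime evaluation compares a day's naps against a single
  following main-sleep start; exotic schedules (two main sleeps in a day,
  shift work) are out of scope.
- The SHACL export is illustrative for non-single-pattern rules; running
  it in an external SHACL engine will not reproduce window or daily
  aggregation semantics.
- No timezone or daylight-saving handling; inputs are assumed to be in
  one consistent local clock.
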