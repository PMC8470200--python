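# wearkg

Knowledge-graph based detection of health-related events from wearable
lifestyle data.

Consumer wearables export per-minute step counts, per-minute heart rate
and session-structured sleep records (stage minutes, awakenings, sleep
efficiency). For clinicians monitoring people with chronic neurological
conditions, the raw charts are hard to read at a glance; what matters is
whether clinically meaningful *events* — too little sleep, severe sleep
fragmentation, sustained inactivity, bradycardia — occurred, and on which
days. `wearkg` implements a symbolic, fully explainable pipeline for this:

1. **Observation modelling.** Every measurement becomes a SOSA-style
   observation `(featureOfInterest, observedProperty, result, phenomenonTime)`
   and is classified into a hierarchy of observation types
   (`MovementObservation`, `WalkingFeature`, `SleepObservation`,
   `HeartObservation`, ...) by forward evaluation of equivalence axioms of
   the form

   ```
   MovementObservation ≡ Observation ⊓ ∃observedProperty.MovementProperty
                                     ⊓ ∃hasFeatureOfInterest.{movement}
   WalkingFeature      ≡ MovementObservation
                         ⊓ ∃observedProperty.{distance, elevation, floors, steps}
   ```

2. **Rule-based detection.** A configurable rule base of twelve strict
   numeric rules — daily aggregates (e.g. *total sleep in a day < 300 min →
   Lack of Sleep*, *steps in a day < 8000 → Lack of Exercise*) and
   heart-rate/step window rules (e.g. *steps < 500 & HR < 100 for
   > 800 min → Lack of Movement*) — runs over the observations.
   Thresholds can be overridden per subject.

3. **Situation modelling.** Each detection is materialised as a *problem
   situation* under the Descriptions-and-Situations pattern
   (`Problem ⊑ Situation ⊓ ∃hasView.View ⊓ ∃interprets.Observation`), so
   the graph records not just *that* an event fired but *which*
   observations it interprets and under which conceptual view. Problems
   are also exported as Web-Annotation records (views → bodies,
   observations → targets) and as a SHACL-SPARQL rules document for
   interoperability.

4. **Reporting and benchmarking.** Dashboard-style resampling
   (minute…year, sum/average), min/avg/max summaries, a problem timeline,
   and a scalability harness for ingestion and rule evaluation.

A seed-reproducible synthetic-data generator produces realistic compliant
subjects and can inject episodes that provably trigger any of the twelve
rules, so the whole pipeline is testable without any real patient data.

## Worked example

```sh
wearkg simulate --days 4 --seed 3 --inject LackOfSleep:2021-03-02 --out-dir data/
wearkg detect --steps data/steps.csv --hr data/hr.csv --sleep data/sleep.json \
              --out-dir out/
```

`out/problems.json` then contains exactly one detected event:

```json
[
  {
    "id": "problem/tms6/LackOfSleep/b5867091c2",
    "problem_type": "LackOfSleep",
    "category": "SleepProblem",
    "subject_id": "tms6",
    "start": "2021-03-02T00:00:00",
    "end": "2021-03-03T00:00:00",
    "interpreted_observation_ids": ["obs/tms6/asleep_duration/20210301T223000"]
  }
]
```

The injected night of 2 March was shortened to 240 minutes of sleep, which
is strictly below the 300-minute daily limit, so the Lack of Sleep rule
fires for that day and interprets the night's `asleep_duration`
observation. The compliant surrounding days produce no events.
`out/graph.ttl` holds the full knowledge graph (observations plus the
problem in DnS shape), `out/annotations.jsonld` the WADM export, and
`out/report.json` the dashboard aggregation.

The same pipeline is available as a library:

```python
from wearkg import SyntheticProfile, generate_subject_days, run_rulebase

data = generate_subject_days(SyntheticProfile(), 14, seed=1)
problems, kg = run_rulebase(data.steps, data.heart_rate, data.sessions)
```

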