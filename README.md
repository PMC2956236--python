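# searchcode

Coding and statistical analysis of clinician search-session logs.

When clinicians answer clinical questions with a search engine, the
interface shapes *how* they search.  With a **resource-based** interface
(pick one of 6 information resources such as PubMed, then type keywords)
users tend toward **breadth-first** behavior — trying new resources while
holding the query fixed.  With a **task-based** interface (pick one of 6
clinical tasks such as diagnosis) they tend toward **depth-first**
behavior — staying in the same profile while reformulating keywords.
`searchcode` turns raw two-arm search-event logs into evidence about
that contrast:

1. **Transition coding.**  Each consecutive-search pair within a session
   gets a profile code (same / previously used / new profile), a
   query-reformulation code (no change / syntactic / semantic / both,
   with syntactic subtypes: capitalization, word order, conjunctions,
   spacing, typographic variants), a combined 4-way action category, and
   a first/middle/last position label.
2. **Inference.**  Coded transitions aggregate into arm-by-category
   contingency tables analyzed with Pearson's χ² =
   Σ (O − E)²/E, per-cell Wilson score intervals
   ((p̂ + z²/2n)/(1 + z²/n) ± z√(p̂(1−p̂)/n + z²/4n²)/(1 + z²/n)), and
   row-wise unpooled two-proportion z-tests
   (z = (p̂₁ − p̂₂)/√(p̂₁(1−p̂₁)/n₁ + p̂₂(1−p̂₂)/n₂)).
3. **Synthesis.**  A behavioral sampler generates logs from a
   probability vector over the 12 profile × reformulation action
   combinations, and an exact-fixture builder constructs logs whose
   coded tables match target counts cell-for-cell — so the whole
   pipeline is testable without access to any original logs.

## Worked example

Build the two-arm fixture carrying the published study counts
(310 resource sessions / 1708 searches; 288 task sessions / 873
searches), run it through the full pipeline, and print the report:

```python
from searchcode import full_report
from searchcode.synthetic import study_fixture_log

log = study_fixture_log()
bundle = full_report(log, out_dir="out")
print(open("out/report.txt").read())
```

The report begins:

```
Search-action coding report
===========================
Sessions: 598   Searches: 2581   Transitions: 1983
  resource: 310 sessions, 1708 searches, 1398 transitions
  task: 288 sessions, 873 searches, 585 transitions

[profile]
  chi-square(2) = 103.45, p = <.001
  same: resource: 557/1398 (39.8%, 95% CI 37.31-42.43)  task: 379/585 (64.8%, 95% CI 60.83-68.55)  Z = -10.53, p = <.001
  previous: resource: 202/1398 (14.4%, 95% CI 12.70-16.39)  task: 55/585 (9.4%, 95% CI 7.29-12.04)  Z = 3.30, p = <.001
  new: resource: 639/1398 (45.7%, 95% CI 43.11-48.33)  task: 151/585 (25.8%, 95% CI 22.43-29.51)  Z = 8.86, p = <.001
```

Reading it: the 1398 resource-arm transitions (1708 searches minus 310
sessions) split 39.8% same / 14.4% previous / 45.7% new profile, while
the task arm keeps the same profile in 64.8% of transitions — the
breadth-first vs depth-first contrast, with χ²₂ = 103.45 confirming the
arms differ.  `out/` also holds `coded_transitions.csv` and one CSV per
table family (profile, query, 12-cell combination, actions by position,
consecutive action pairs).

The same pipeline runs from the shell:

```sh
searchcode simulate --arm resource --preset study --out resource.jsonl
searchcode simulate --arm task --preset breadth --seed 7 --out sampled.jsonl
searchcode code --log resource.jsonl --out out/
searchcode stats --table my_counts.csv
```

`--preset study` writes the exact published-count fixture;
`breadth`/`depth` sample from the behavioral presets.  Logs are JSONL
(one event per line: participant, session, arm, 1-based sequence index,
profile, and the four keyword fields) or an equivalent flat CSV; both
round-trip exactly.

Classify a single reformulation directly:

```python
>>> from searchcode import classify_query_reformulation
>>> kw = lambda d, s="": {"disease": d, "drug": "", "symptom": s, "other": ""}
>>> code = classify_query_reformulation(kw("asthma"), kw("Asthma child"))
>>> code.value.value, sorted(s.value for s in code.subtypes)
('syntactic_and_semantic', ['capitalization'])
```

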