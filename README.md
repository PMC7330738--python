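# symptom-sentinel

A rule-based engine for monitoring daily patient-reported symptom reports
in post-surgical cancer follow-up. Patients rate each symptom's occurrence
(yes/no) and, when present, its frequency and distress on 4-point ordinal
scales. Reports are evaluated against a phase-dependent risk-assessment
ruleset — one rule panel after surgery, another during adjuvant
chemotherapy — that maps (symptom, rated dimension, qualifying responses,
consecutive-day window) to a red or yellow alert. Red alerts demand
contact within one hour, yellow alerts the same working day; alerts raised
outside clinic hours are deferred to the next working day.

The package provides:

- **`sentinel.rules`** — symptom catalog, rating scales, and alert rules,
  with a YAML config dialect and a built-in pancreatic-surgery ruleset
  (15 post-surgery rules with 1/2/3/7-day windows; 15 single-report
  chemotherapy rules).
- **`sentinel.reports`** — patient profiles, daily reports, advice-view
  events; canonicalization (one report per patient-day, latest submission
  wins); JSON-lines and long-CSV readers/writers.
- **`sentinel.engine`** — streak-based alert evaluation: calendar-
  consecutive run-lengths per rule, missed days break streaks, red
  supersedes yellow for the same symptom-day, deterministic alert ids.
  Policy switches select daily re-triggering (default) or once-per-episode
  firing.
- **`sentinel.scheduling`** — contact tasks with working-hours deadlines
  (default 08:00–16:00, Mon–Fri, optional holidays).
- **`sentinel.analytics`** — adherence (days reported / days expected),
  half-up percentage arithmetic, and per-symptom / per-alert / per-advice
  summary tables.
- **`sentinel.cohort`** — a seeded synthetic cohort generator (two-state
  Markov symptom persistence, missed days, mid-stream phase switches) and
  a brute-force window-scan oracle used to verify the engine.

## CLI

The `sentinel` entry point chains the pipeline:

```sh
sentinel ruleset show --builtin pancreas > rules.yaml
sentinel ruleset validate rules.yaml

sentinel simulate --seed 17 --out-dir sim/          # synthetic cohort
sentinel reports validate sim/reports.csv

sentinel evaluate --reports sim/reports.csv --profiles sim/profiles.csv \
                  --out alerts.csv
sentinel schedule --alerts alerts.csv --out contacts.csv
sentinel summarize --reports sim/reports.csv --profiles sim/profiles.csv \
                   --alerts alerts.csv --views sim/advice_views.csv \
                   --out-dir summaries/
```

`sentinel run --config run.yaml` executes evaluate → schedule → summarize
in one shot and writes a manifest with output checksums; re-running the
same config reproduces the checksums byte for byte.

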