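# medwindow

Decision-support engine for missed antihypertensive doses. A curated
formulary assigns every medication × dosing-frequency pair a **safe
window** — the number of hours after the intended dose time during which a
missed dose may still be taken without overdose concern. The engine turns a
prescription into routine-anchored dose slots, classifies any instant
against each slot's dosing window (which opens 1 hour before the intended
time and closes at the end of the safe window), and drives the
take/snooze/skip state machine:

- **UPCOMING** — the window has not opened yet; no actions are offered.
- **ACT_NOW** — inside the window: *take*, *snooze* (another reminder in
  15 minutes, at most 4 consecutive snoozes), or *skip*.
- **OVERDUE** — past the window: *skip* is recommended, but the user may
  still take; an overdue take raises a take-or-skip prompt on the next
  scheduled dose so a double dose is never taken silently.

State is an append-only event log (JSON Lines); adherence summaries and a
seeded behavior simulator are built on top, so every rule is exercisable
without patient data.

## Layout

| Module                 | Contents |
|------------------------|----------|
| `medwindow.formulary`  | `MedicationEntry`, `Formulary`, CSV/JSON load/validate/write, name + brand lookup |
| `medwindow.schedule`   | `Regimen`, `DoseSlot`, window computation, DST-aware slot generation |
| `medwindow.engine`     | `classify`, `available_actions`, the event-sourced `Engine`, expiry |
| `medwindow.adherence`  | `summarize` → `AdherenceSummary` |
| `medwindow.simulator`  | `BehaviorModel`, `simulate`, `generate_synthetic_formulary` |
| `medwindow.cli`        | `medwindow` console entry point |

A 21-row published-excerpt formulary ships at
`src/medwindow/data/safe_windows_example.csv` and is the default for all
CLI commands.

## CLI

```sh
medwindow validate path/to/formulary.csv        # exit 0 iff clean
medwindow lookup Norvasc 1                      # brand resolves to generic
medwindow classify amlodipine 1 --intended 08:00 --now 10:00   # -> ACT_NOW
medwindow simulate --config examples/bid_3h_scenario.yaml --out events.jsonl
medwindow summarize --config examples/bid_3h_scenario.yaml --events events.jsonl
```

All outputs are JSON (`--pretty` for humans); exit codes are 0 (ok),
1 (domain error), 2 (usage error). `examples/bid_3h_scenario.yaml` is the
canonical twice-daily, 3-hour-window scheduling scenario.

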