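# Canonical scheduling scenario: a medication taken twice daily with a
# 3-hour safe window.  Dosing windows: [07:00, 11:00) and [19:00, 23:00).
formulary: scenario_formulary.csv
regimen:
  medication: examplol
  frequency_per_day: 2
  dose: [50]
  anchor_times: ["08:00", "20:00"]
  anchor_labels: ["breakfast", "dinner"]
  timezone: America/New_York
  start_date: 2025-01-06
model:
  open_probability: 0.9
  delay:
    kind: lognormal
    median_minutes: 5
    sigma: 2.0
  overdue_take_probability: 0.25
  snooze_probability: 0.2
  seed: 20250106
n_days: 14
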