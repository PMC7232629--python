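levels:
- '0'
- 1a
- 1b
- '2'
- '3'
multipliers:
- 0.99
- 1.39
- 1.72
- 1.97
- 5.96
uplift_fraction: 0.22
wte_weekly_hours: 37.5
specialing_hours_per_patient_day: 24.0
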