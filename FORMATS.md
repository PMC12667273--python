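# File formats

All interchange is plain CSV with ISO-8601, timezone-aware timestamps.
Times of day for sleep parameters are **minutes past the preceding
noon** (so an onset of 690 means 23:30 local time), which keeps each
night's onset and wake on one monotone axis across midnight.

## Raw accelerometer stream (`raw/<participant_id>.csv`)

| column      | type    | units | notes                                   |
|-------------|---------|-------|-----------------------------------------|
| `timestamp` | ISO-8601| -     | strictly increasing; naive values are localized to the CLI `--tz` (default `Europe/London`) |
| `x`,`y`,`z` | float   | g     | tri-axial acceleration, \|a\| < 16 g    |

Recordings span up to 9 days at a nominal rate of at least 20 Hz.

## Sleep table (`sleep_table.csv`)

One row per participant-night (detected, adjusted major sleep episode).

| column          | type  | units  | notes                               |
|-----------------|-------|--------|-------------------------------------|
| `participant_id`| str   | -      |                                     |
| `night_index`   | int   | -      | 1..7 within the recording           |
| `date`          | date  | -      | label date (wake day by default)    |
| `dow`           | str   | -      | `Mon`..`Sun` of the label date      |
| `onset_min`     | float | min    | minutes past the night's noon anchor|
| `wake_min`      | float | min    | same convention                     |
| `duration_min`  | float | min    | `wake_min - onset_min`              |
| `qc_flags`      | str   | -      | `;`-joined per-night flags, may be empty |

Round-trips losslessly through `somnarc.io.write_sleep_table` /
`read_sleep_table`.

## Participants / QC table (`participants.csv`, `qc.csv`)

`participant_id`, `age` (years), `sex` (`XX`/`XY`), `age_bin`
(`44-49` .. `75-82`), and after detection additionally
`wake_activity` (mean worn-minute activity power outside sleep, g),
`n_nights`, `qc_pass` (bool), `qc_reasons` (`;`-joined reason codes
from `duplicate`, `structural_anomaly`, `missing_days_gt4`,
`midweek_wristoff`, `dst_overlap`, `short_record`).

## Self-reports (`self_reports.csv`)

`participant_id`, `reported_hours` (integer 3..12),
`too_much_sleep` / `waking_too_early` (`Yes`/`No`),
`depression` / `anhedonia` (one of `not at all`, `several days`,
`more than half the days`, `nearly every day`).

## Summary tables (`group_summaries.csv`, `contrasts.csv`, ...)

Tidy tables with one row per stratum x parameter: `sex`, `age_bin`,
`parameter`, `n`, `mean`, `se`, `pct_of_total` (percent of the cohort,
2 decimals); contrasts additionally carry `mean_diff`, `t`, `df`,
`p_value`, `significant`.

## Configuration YAML

`PipelineConfig` fields (see `somnarc/config.py`) for the detection
pipeline; `CohortModel` fields (see `somnarc/synthetic.py`) for the
generator. Unknown keys are rejected, never silently ignored.
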