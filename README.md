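# somnarc

Actigraphy sleep analysis for large cohorts: detect each night's major
sleep episode from raw wrist-worn accelerometer data, apply cohort
quality control, and compute age- by sex-stratified statistics of sleep
timing, duration, activity, and their associations with self-reported
sleep and mood.

It is written for researchers working with week-long wrist
accelerometry (e.g. population biobank deployments of tri-axial
wristbands sampled at 20–100 Hz) who need objective sleep parameters
without polysomnography, plus the descriptive statistics that typically
accompany them. Because such cohort data cannot be redistributed, the
package includes a first-class synthetic cohort generator with known
ground-truth schedules, so the entire chain is testable by parameter
recovery.

## The method

**Detection.** For each participant the raw signal is resampled to
20 Hz; off-wrist minutes are flagged where 150-min forward/backward
means of the per-minute acceleration SD fall below a stillness bound;
each minute's activity power is the integrated power density spectrum
of the mean-removed signal across the three axes (Parseval-equivalent
to its RMS). Minutes are then ranked into within-person percentile
categories (5..100 by 5). Candidate sleep is seeded at low categories
and stabilized by forward/backward moving averages of 100, 60 and
90 min; in every noon-to-noon window the longest candidate run is the
night's raw sleep episode — no prior assumption about bedtime or
duration — and hierarchical merge/trim/extend rules using the
10th/25th/50th percentile categories yield the adjusted episode.

**Statistics.** One value per participant per parameter (nights are not
treated as independent), then per-stratum n / mean / SE, within-person
weekday–weekend contrasts (paired t), OLS age trends on bin midpoints
(linear vs quadratic R²), Cohen's d with 95% CI, pooled-variance
two-sample t-tests and one-way ANOVA at α = 0.05 per contrast.

See `docs/methods.md` for the model, parameter defaults and their
rationale, and `FORMATS.md` for all file schemas.

## Worked example

Simulate a two-sex, under-60 cohort, run detection and QC, and
summarize:

```python
from somnarc import CohortModel
from somnarc.analysis import summarize_groups
from somnarc.pipeline import (run_synthetic_study, under60_sex_duration_gap,
                              mean_weekend_contrast)

model = CohortModel(n_per_cell=100, age_bins=[(44, 49), (50, 54), (55, 59)],
                    seed=11)
study = run_synthetic_study(model)

parts = study["participants"]
ok = parts[parts.qc_pass]
nights = study["nights"]
nights = nights[nights.participant_id.isin(ok.participant_id)]
print(f"{len(parts)} simulated, {len(ok)} pass QC")
print(summarize_groups(nights, ok).query("parameter == 'duration'")
      .to_string(index=False))
print("sex gap: %.1f min" % under60_sex_duration_gap(study)[0])
print("weekend contrast: %.1f min" % mean_weekend_contrast(study)[0])
```

which prints:

```
600 simulated, 594 pass QC
sex age_bin parameter   n       mean       se  pct_of_total
 XX   44-49  duration  98 462.784257 2.068720         16.50
 XX   50-54  duration  97 467.353461 1.913826         16.33
 XX   55-59  duration 100 460.848571 1.781568         16.84
 XY   44-49  duration 100 446.662857 1.984440         16.84
 XY   50-54  duration 100 457.307143 1.978025         16.84
 XY   55-59  duration  99 444.959596 1.794055         16.67
sex gap: 14.0 min
weekend contrast: 47.4 min
```

Six participants fail QC (mid-week off-wrist time). Each row is a
sex × age-bin stratum: the mean detected sleep duration in minutes with
its standard error across participants, and the stratum's share of the
cohort. Female strata sleep ~14 min longer than male strata here — the
end-to-end estimate of the generator's 17-min gap at this small n (SE
≈ 2.7 min) — and sleep on weekend nights runs ~47 min longer than on
weekday nights, recovering the generator's 50-min weekend shift.

The same stages are available from the shell:

```bash
somnarc simulate --config model.yaml --out sim/ --seed 11
somnarc detect --raw sim/raw/ --out sleep_table.csv --qc-out qc.csv
somnarc split --qc-pass qc.csv --seed 1 --out splits.csv
somnarc summarize --sleep-table sleep_table.csv --participants qc.csv --out report/
somnarc run --config model.yaml --out full_run/ --seed 11   # all stages
```

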