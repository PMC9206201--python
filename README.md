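# rhinodiary

Analysis pipeline for daily allergic-rhinitis symptom diaries: daily
score construction, adherence-to-recording measurement, per-patient
data-quality indices, and the comparison of those indices between high-
and low-adherence patients. A fully parameterised synthetic cohort
generator (with ground-truth responder-behaviour labels) makes every
stage testable without access to clinical data.

## What it computes

**Daily scores** from item-level diary entries (six symptom items graded
0–3, three medication flags, a 0–10 VAS):

- **RTSS** — total symptom score, sum of the six grades (0–18);
- **CSMS** — combined symptom and medication score: mean of the six
  grades (0–3) plus a medication score (0–3 from a drug-class
  hierarchy), range 0–6, unit step 1/6;
- **VAS** — the daily 0–10 self-rating.

**Adherence** — percentage of prescribed monitoring days with a
completed entry; patients at or above 80% (configurable) form the
high-adherence group. Pooled (total/total) and mean-of-individual
percentages are reported separately, along with delayed-start /
early-end detection (≥3 days).

**Quality indices** per patient and score trajectory:

- intravariation index — % of consecutive-day pairs with a value change,
  divided by the individual variation range in unit steps (max−min)/S;
- % of zero values;
- coefficient of variation (100·SD/mean);
- % of changes in trend — share of transitions between successive
  day-to-day difference signs (+/0/−).

**Cohort statistics** — per-date population score means, Spearman
correlations of per-patient mean scores, mean (95% CI) index summaries,
and two-sided Mann–Whitney U comparisons of every (score, index) pair
between adherence groups (exact p for small untied samples).

**Synthetic cohorts** — a pollen-season simulator with per-patient
sensitivity, ordinal symptom thresholds, persistent medication uptake,
bursty recording with optional delayed start/early stop, and a
"carry-forward" (insufficient-effort) responding style whose prevalence
can be linked to low adherence. With the default linkage, the
trend-change index separates the adherence groups while the other three
indices mostly do not — the structure the pipeline is designed to
detect.

## Command line

```bash
# simulate a 101-patient, 56-day cohort
rhinodiary simulate --out-dir data/ --seed 1

# individual stages
rhinodiary score     --diary data/diary.csv --windows-file data/windows.csv --out scores.csv
rhinodiary adherence --diary data/diary.csv --windows-file data/windows.csv --out adherence.csv
rhinodiary indices   --diary data/diary.csv --windows-file data/windows.csv --out indices.csv
rhinodiary compare   --diary data/diary.csv --windows-file data/windows.csv --out table3.csv

# full pipeline: scores, adherence, indices, summaries, comparisons,
# correlations, population trajectories and a JSON run log
rhinodiary report --diary data/diary.csv --windows-file data/windows.csv --out-dir report/
```

A global window can be given instead of a window file with
`--window-start 2016-05-04 --window-end 2016-06-28`. Analysis options
(threshold, pairing mode, variation-range variant, trend mode, SD
denominator) can be set in a YAML config passed via `--config-file`;
defaults follow the reference choices.

## Layout

| Module | Purpose |
| --- | --- |
| `rhinodiary.diary` | domain types (diary day, monitoring window, patient series) and delimited-text I/O |
| `rhinodiary.scoring` | RTSS/CSMS/VAS and score trajectories |
| `rhinodiary.adherence` | per-patient and pooled adherence, high/low classification, start/end deviations |
| `rhinodiary.quality` | the four per-patient quality indices |
| `rhinodiary.cohort` | population trajectories, correlations, index summaries, adherence-group comparison |
| `rhinodiary.simulate` | synthetic cohort generator with ground-truth labels |
| `rhinodiary.config`, `rhinodiary.pipeline`, `rhinodiary.cli` | configuration, orchestration, command line |
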