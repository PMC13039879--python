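# oddpupil

Trial-level analysis pipeline for concurrent pupillometry and EEG during a
passive auditory oddball task, with a synthetic-data generator standing in
for raw recordings.

The pipeline covers:

- **task_design** — oddball schedule generation: 4 blocks x 103 trials
  (3 leading standards + 100 pseudorandom tones, 80/20 standard/oddball),
  100 ms tones, 1800–2000 ms jittered ISI, 500/750 Hz pitches
  counterbalanced within subjects around a mid-task manipulation.
- **synthetic_data** — sample-level two-eye pupil traces (300 Hz) with
  tonic drift, a gamma-shaped evoked dilation, blinks and speed-spike
  artifacts; five-channel ERP epochs (500 Hz, −500…800 ms) with negative
  (100–150 ms) and positive (150–250 ms) deflections plus 1/f noise;
  per-subject random effects and configurable group x phase effect
  structure. Ground truth is recorded per trial for recovery testing.
- **pupil_prep** — the preprocessing chain: 2–8 mm range filter,
  two-pass dilation-speed MAD outlier filter, blink detection (75–250 ms
  gaps, 27 ms padding), linear interpolation of gaps ≤ 300 ms, eye
  averaging, subtractive baseline correction over 0–250 ms (BPS), mean
  corrected dilation over 500–1500 ms (SEPR), 50% validity rule.
- **erp** — 30 Hz zero-phase Butterworth low-pass, pre-stimulus baseline,
  cluster averaging, windowed MMN/P3a peak extraction (±4 ms mean
  amplitude + latency), difference waves, 2/3 block-inclusion rule
  (13 oddballs / 53 standards).
- **trial_model** — REML linear mixed models with a participant random
  intercept (`outcome ~ stimulus * group * manipulation + block_direction
  + age + gender`), grand standardization of outcomes, marginal-mean
  contrasts with delta-method CIs, Nakagawa marginal/conditional R², and
  pupil-to-ERP coupling models.
- **power_sim** — Monte-Carlo power for the group x manipulation
  interaction (Wald test of the omnibus interaction in the trial-level
  random-intercept model; Wilson binomial CI on power).
- **cli_io** — TSV/CSV/HDF5/YAML I/O, config validation, the end-to-end
  pipeline and a JSON run manifest with seeds and file hashes.

## Command line

All commands are subcommands of `oddpupil`:

```bash
oddpupil simulate-schedule --seed 1 --subjects 10 --out schedule.tsv
oddpupil run-all --config config.yaml --out results/
oddpupil preprocess-pupil --in samples.tsv --schedule schedule.tsv --out pupil.csv
oddpupil extract-erp --in epochs.h5 --out erp.csv --diff-out diffwave.csv
oddpupil fit-models --trials trial_features.csv --out models/
oddpupil power --beta 0.2 --n 150 --groups 52,55,43 --reps 200 --seed 1 --out power.json
```

A minimal YAML config needs only a seed:

```yaml
seed: 1
n_per_group: [4, 4, 4]
outcomes: [bps, sepr, mmn_amp, p3a_amp]
```

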