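# motorsig

A tested pipeline for detecting a two-group motor signature in tablet
card-dragging movements:

1. **`motorsig.synthetic`** — generates touch-stream cohorts with the study
   design (two equal groups, 5 subtests x 5 items per subject, 40 Hz touch
   sampling on a 1280 x 800 screen) from a goal-attracted correlated-walk
   motion model. Group contrasts (straightness, directional change, bout
   length, speed spread, fragmentation) are planted via latent subject
   parameters; presets: `default` (planted signal) and `null` (identical
   groups).
2. **`motorsig.trajectories`** — segments each stream into finite
   trajectories (press .. release), with an auditable discard log.
3. **`motorsig.features`** — 12 per-task kinematic features (MeanSpeed,
   MaxSpeed, MinSpeed, sdSpeed, MeanAcceleration, MaxAcceleration,
   MinAcceleration, sdAcceleration, STH, DC, sdDC, MeanLength) plus 5
   subtest indicators; dataset assembly and z-score standardization.
4. **`motorsig.mlp`** — a from-scratch 17–H–2 feedforward network
   (tanh hidden layer, softmax output, Xavier init, full-batch Adam,
   lr 0.01, 500 epochs), metrics (confusion, sensitivity/specificity,
   ROC/AUC), repeated k-fold cross-validation (default 10-fold x 5) and a
   descending hidden-size grid search with a parsimony rule.
5. **`motorsig.ablation`** — greedy backward input ablation: repeatedly
   masks the least-impactful kinematic input of the trained network (no
   retraining) and records the metrics-vs-retained-features curve.
6. **`motorsig.pipeline` / `motorsig.cli`** — one-config orchestration with
   seed fan-out, CSV/JSON artifacts and a checksum manifest.

## CLI

```bash
motorsig simulate  --seed 1 --n-per-group 30 --preset default --out touch_log.csv
motorsig featurize --touch-log touch_log.csv --out features.csv
motorsig train     --features features.csv --seed 1 --out-dir model/
motorsig evaluate  --model model/model.json --features features.csv --out metrics.json
motorsig ablate    --model model/model.json --features features.csv \
                   --test-idx model/best_test_idx.csv --out ablation.csv
motorsig run-all   --seed 1 --out-dir run/        # everything + manifest.json
```

`run-all` writes `touch_log.csv`, `features.csv`, `scaler.yaml`,
`cv_metrics.json`, `roc.csv`, `training_trace.csv`, `ablation.csv` and a
`manifest.json` with SHA-256 checksums; identical config + seed reproduces
identical checksums.

## Notes on protocol choices

- Cross-validation `split_mode="sample"` randomises over rows, so one
  subject's tasks may span folds (this leaks subject identity between train
  and test); `split_mode="subject"` keeps each subject in one fold and is
  used for null-calibration checks.
- Standardization default is whole-dataset before splitting
  (`standardize_mode="whole"`); a leakage-safe `"per-fold"` mode is
  available.
- `MeanLength` is the mean per-bout path length; the per-task bout *count*
  is surfaced separately as `TaskFeatureVector.n_trajectories` (diagnostic
  only, not a model input).
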