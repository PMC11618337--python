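# reachkin

Kinematic analysis of wrist-worn IMU displacement during reach-and-place
movements: synthetic cohort simulation, extraction of twelve per-trial
kinematic parameters, nonparametric group statistics, and an MLP
classification protocol with permutation feature importance.

## What it does

- **`reachkin.trajectory_io`** — trial containers and CSV I/O (long-format
  trials, wide-format feature tables) plus a rigid common-reference-frame
  transform (translate to origin, principal axis to +X).
- **`reachkin.synthetic_data`** — a generative model for reach-and-place
  trials built from minimum-jerk segments: a primary reach with
  configurable time-to-peak asymmetry, an overshoot excursion, Poisson-many
  corrective submovements, and additive positional noise. Cohorts carry
  subject-level random effects and per-trial ground truth (onset,
  submovement count, amplitude), and a score generator produces per-subject
  adaptive-functioning covariates with configurable loadings.
- **`reachkin.kinematics`** — zero-phase Butterworth smoothing, central
  differences, movement-onset detection (simultaneous 20 %-of-maximum rule
  on distance-from-start and acceleration, refined to the start of the
  speed rise), and the twelve parameters: reaction time, movement time,
  total distance, average/maximum velocity and acceleration, times to both
  peaks, and RMS movement-unit counts of Types 1–3 (zero-crossings of
  velocity, acceleration and jerk per axis, RMS-consolidated).
- **`reachkin.group_stats`** — Mann-Whitney U (exact for small tie-free
  samples), Brown-Forsythe Levene and one-sample KS assumption checks,
  Pearson correlations against per-subject covariates, and
  Benjamini-Hochberg FDR flags applied per (group × covariate) family.
- **`reachkin.classifier`** — min-max normalization, a numpy MLP (four
  fully connected layers 9→64→32→16→1, three batch norms, three leaky
  ReLUs, sigmoid output) trained 200 epochs with ADAM at lr 1e-5 dropping
  to 1e-6 once training accuracy reaches 95 %, stratified ten-fold
  cross-validation (trial- or subject-grouped folds), and permutation
  feature importance (mean permuted validation loss minus best validation
  loss).
- **`reachkin.cli`** — pipeline orchestration with plain CSV/JSON artifacts
  and a Markdown report.

## CLI

```sh
reachkin run --config configs/default.yaml --seed 1 --out runs/demo
# or stage by stage:
reachkin simulate --config configs/default.yaml --seed 1 --out runs/demo
reachkin extract  --config configs/default.yaml --seed 1 --out runs/demo
reachkin stats    --config configs/default.yaml --seed 1 --out runs/demo
reachkin classify --config configs/default.yaml --seed 1 --out runs/demo
reachkin report   --config configs/default.yaml --seed 1 --out runs/demo
```

Artifacts written per stage: `trials.csv` (+ JSON sidecar),
`ground_truth.csv`, `scores.csv`, `features.csv`, `group_stats.csv`,
`correlations.csv`, `cv_result.json`/`.csv`, `importance.csv`, `report.md`
and a `manifest.json` recording seed and config hash. A run is reproducible
from config + seed alone.

## Notes on protocol choices

- Whole-dataset min-max normalization and trial-level CV folds replicate
  the original protocol, including its leakage; `normalization: fold` and
  `grouping: subject` are the recommended leak-free alternatives and both
  are first-class options.
- Accuracy is reported with per-class sensitivity/specificity, since a
  65/35 class imbalance makes raw accuracy optimistic.
- Mini-batch size is the one free parameter of the published training
  schedule; 8 is used in the acceptance protocol so that 200 epochs at
  lr 1e-5 converge on separable data (the default remains 32).
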