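# squatform

Squat-posture classification from wearable inertial sensors, as a
tested, reproducible pipeline.

## The problem

Inexperienced exercisers performing squats risk spinal and knee
injuries when their form degrades. Six canonical forms are
distinguished: an acceptable squat (ACC) and five aberrant ones —
anterior knee (AK, knees ahead of toes), knee valgus (KVG, knees
inward), knee varus (KVR, knees outward), half squat (HS, insufficient
depth), and bent over (BO, excessive hip/torso flexion). Body-worn
6-axis inertial measurement units (IMUs: 3-axis accelerometer ±2 g,
3-axis gyroscope ±500 °/s) on the lumbar region, thighs, and calves
record each trial of six ~3 s repetitions; the task is to classify the
form of each repetition and to ask which sensor placement carries the
most information.

`squatform` implements the full analysis for researchers in wearable
movement analysis:

* **simulate** — a kinematic forward model (3-link sagittal chain +
  frontal-plane channel) that generates labeled multi-sensor trials
  with ground-truth repetition boundaries, emulating a 39-subject
  study design (39 × 6 forms × 6 reps = 1404 repetitions).
* **segment** — repetition extraction via the Hilbert transform: the
  right-thigh roll angle is estimated by complementary-filter fusion,
  the unwrapped analytic-signal phase delimits the six cycles, the
  same windows cut every synchronized sensor, and each segment is
  resampled to 40 points, giving a 6×40 matrix per sensor.
* **features** — the conventional branch: 11 statistics (mean, median,
  max, min, SD, RMS, range, 25th/75th percentile, skewness, kurtosis)
  × 6 axes = 66 features per IMU, classified by a bagged decision-tree
  (random forest) ensemble.
* **convlstm** — the deep branch: a CNN–LSTM (three 3×3 conv layers,
  channels 8→16→32, 1×2 time-axis max-pooling, a 64-cell LSTM, dense +
  softmax) trained with Adam (lr 0.001, cross-entropy); three models
  with different initializations and input orders are ensembled by
  averaging their softmax outputs. Implemented in NumPy with
  hand-derived, gradient-checked backpropagation.
* **evaluate** — subject-wise 10-fold cross-validation (no subject
  appears in both train and test), pooled 6×6 confusion matrices,
  accuracy / macro sensitivity / macro specificity, and the
  placement-combination experiment (5 IMUs, three pairs, three
  singles × both branches = 14 reports).

See `docs/methods.md` for the models, defaults, and limitations.

## Worked example

```python
import numpy as np
from squatform import simulate, segment, evaluate
from squatform.core import SensorPlacement

# simulate a 10-subject study and segment it
trials = simulate.generate_dataset(
    10, master_seed=3, placements={SensorPlacement.RIGHT_THIGH})
reps = segment.segment_dataset(trials)
print(len(trials), "trials ->", len(reps), "repetitions")

# subject-wise cross-validation of the feature/forest branch
folds = evaluate.make_subject_folds(
    sorted({r.subject_id for r in reps}), n_folds=5, rng_seed=3)
report = evaluate.cross_validate(
    reps, [SensorPlacement.RIGHT_THIGH], "cml", folds,
    rng_seed=3, branch_options={"n_trees": 200})
print(f"accuracy {report.accuracy:.1f}%  "
      f"sensitivity {report.sensitivity:.1f}%  "
      f"specificity {report.specificity:.1f}%")
```

prints

```
60 trials -> 360 repetitions
accuracy 95.8%  sensitivity 95.8%  specificity 99.2%
```

360 = 10 subjects × 6 forms × 6 repetitions: every repetition was
found and extracted. The accuracy is pooled over held-out subjects
only — 95.8% against a 16.7% six-class chance level — and macro
sensitivity/specificity are one-vs-rest averages over the six forms.
Residual errors concentrate among ACC/AK/BO, whose right-thigh
kinematics are most alike across movers of different squat depth.  The scripts in `examples/`
walk through each stage the same way (simulation, segmentation,
both classifiers, placement comparison), and the `squatform` CLI
(`squatform run-all --subjects 39 --out runs/full`) executes the whole
pipeline with artifacts on disk.

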