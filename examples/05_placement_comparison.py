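"""Compare sensor placements: which single sensor classifies best?

Runs the statistical-feature branch over the three single-sensor
placements of the study design (right thigh, right calf, lumbar) on a
small cohort, reproducing the qualitative placement ordering: the
right thigh carries the most form information, the lumbar region the
least.  The full 7-combination x 2-branch matrix is available via
`evaluate.run_experiment_matrix`.
"""

from squatform import evaluate, segment, simulate
from squatform.core import SensorPlacement

trials = simulate.generate_dataset(10, master_seed=12)
reps = segment.segment_dataset(trials)
folds = evaluate.make_subject_folds(
    sorted({r.subject_id for r in reps}), n_folds=5, rng_seed=12
)

print(f"{'placement':<14} {'accuracy':>9} {'sensitivity':>12} {'specificity':>12}")
for site in (
    SensorPlacement.RIGHT_THIGH,
    SensorPlacement.RIGHT_CALF,
    SensorPlacement.LUMBAR,
):
    report = evaluate.cross_validate(
        reps, [site], "cml", folds, rng_seed=12,
        branch_options={"n_trees": 200},
    )
    print(
        f"{site.value:<14} {report.accuracy:>8.1f}% "
        f"{report.sensitivity:>11.1f}% {report.specificity:>11.1f}%"
    )

print(
    "\nThe thigh sees the large sagittal excursion plus the frontal"
    "\nvalgus/varus channel; the lumbar sensor alone cannot separate"
    "\nforms that differ below the hip, so its accuracy is lowest."
)
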