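"""Subject-wise cross-validation and placement-combination evaluation.

Subjects are partitioned into folds (10 by default) so that every
repetition of a subject stays on one side of each train/test split —
no individual contributes to both training and test data.  Each fold
is held out once; held-out predictions are pooled into a single 6x6
confusion matrix from which accuracy, macro sensitivity, and macro
specificity are reported (percentages).  Sensitivity and specificity
are unweighted means of the per-class one-vs-rest recall and
true-negative rate.

The placement-combination experiment mirrors the study design: all
five sensors; the pairs (right thigh + lumbar), (right thigh + right
calf), (right calf + lumbar); and the singles right thigh, right calf,
lumbar — each with both the statistical-feature/random-forest branch
(CML) and the CNN-LSTM ensemble branch (DL).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import convlstm, features
from .core import FORM_ORDER, PLACEMENT_ORDER, SensorPlacement
from .segment import Repetition

__all__ = [
    "FoldAssignment",
    "ClassificationReport",
    "CMLBranch",
    "DLBranch",
    "COMBINATIONS",
    "make_subject_folds",
    "cross_validate",
    "metrics_from_confusion",
    "run_experiment_matrix",
    "reports_to_frame",
]

#: The placement combinations evaluated in the study, in table order.
COMBINATIONS: tuple[tuple[SensorPlacement, ...], ...] = (
    PLACEMENT_ORDER,
    (SensorPlacement.RIGHT_THIGH, SensorPlacement.LUMBAR),
    (SensorPlacement.RIGHT_THIGH, SensorPlacement.RIGHT_CALF),
    (SensorPlacement.RIGHT_CALF, SensorPlacement.LUMBAR),
    (SensorPlacement.RIGHT_THIGH,),
    (SensorPlacement.RIGHT_CALF,),
    (SensorPlacement.LUMBAR,),
)

FoldAssignment = dict[int, int]


@dataclass
class ClassificationReport:
    """Pooled evaluation result for one (placement combination, branch)."""

    placement_combination: tuple[SensorPlacement, ...]
    branch: str
    confusion: np.ndarray
    accuracy: float
    sensitivity: float
    specificity: float
    n_folds_evaluated: int = 0

    @property
    def n_total(self) -> int:
        return int(self.confusion.sum())


def make_subject_folds(
    subject_ids: list[int], n_folds: int = 10, rng_seed: int = 0
) -> FoldAssignment:
    """Seeded shuffle + round-robin partition of subjects into folds.

    Fold sizes differ by at most one (39 subjects, 10 folds -> nine
    folds of 4 and one of 3).  Raises if there are fewer subjects than
    folds.
    """
    ids = list(dict.fromkeys(subject_ids))
    if n_folds > len(ids):
        raise ValueError(
            f"n_folds ({n_folds}) exceeds number of subjects ({len(ids)})"
        )
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(ids))
    return {ids[j]: int(i % n_folds) for i, j in enumerate(order)}


def metrics_from_confusion(cm: np.ndarray) -> tuple[float, float, float]:
    """(accuracy, macro sensitivity, macro specificity), as percentages.

    Per class k: sens_k = TP/(TP+FN), spec_k = TN/(TN+FP); macro means
    are unweighted over classes.  A class with zero actual instances is
    excluded from the macro means with a warning.
    """
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    accuracy = 100.0 * np.trace(cm) / total
    sens, spec = [], []
    for k in range(cm.shape[0]):
        tp = cm[k, k]
        fn = cm[k].sum() - tp
        fp = cm[:, k].sum() - tp
        tn = total - tp - fn - fp
        if tp + fn == 0:
            warnings.warn(
                f"class {k} has no actual instances; excluded from macro means",
                stacklevel=2,
            )
            continue
        sens.append(100.0 * tp / (tp + fn))
        spec.append(100.0 * tn / (tn + fp))
    return accuracy, float(np.mean(sens)), float(np.mean(spec))


# ---------------------------------------------------------------------------
# Branches: anything with fit(train_reps, placements) / predict(test_reps).

class CMLBranch:
    """Statistical features + random forest."""

    name = "CML"

    def __init__(self, cfg: features.ForestConfig | None = None):
        self.cfg = cfg or features.ForestConfig()
        self.model = None

    def fit(self, reps: list[Repetition], placements) -> None:
        X = np.vstack([features.extract_features(r, placements) for r in reps])
        y = [r.form.value for r in reps]
        self.model = features.train_forest(X, y, self.cfg)
        self._placements = placements

    def predict(self, reps: list[Repetition]) -> np.ndarray:
        X = np.vstack(
            [features.extract_features(r, self._placements) for r in reps]
        )
        return np.argmax(features.predict_forest(self.model, X), axis=1)


class DLBranch:
    """CNN-LSTM 3-model ensemble on raw stacked matrices."""

    name = "DL"

    def __init__(
        self,
        train_cfg: convlstm.TrainConfig | None = None,
        spec_kwargs: dict | None = None,
    ):
        self.train_cfg = train_cfg or convlstm.TrainConfig()
        self.spec_kwargs = spec_kwargs or {}
        self.model = None

    def fit(self, reps: list[Repetition], placements) -> None:
        X, y = convlstm.stack_dataset(reps, placements)
        spec = convlstm.NetworkSpec(
            input_rows=X.shape[1], input_cols=X.shape[2], **self.spec_kwargs
        )
        self.model = convlstm.train_ensemble(spec, X, y, self.train_cfg)
        self._placements = placements

    def predict(self, reps: list[Repetition]) -> np.ndarray:
        X, _ = convlstm.stack_dataset(reps, self._placements)
        return np.argmax(convlstm.predict_ensemble(self.model, X), axis=1)


def _make_branch(branch, rng_seed: int, branch_options: dict | None):
    opts = dict(branch_options or {})
    if branch == "cml":
        cfg = features.ForestConfig(
            n_trees=opts.get("n_trees", 500),
            max_depth=opts.get("max_depth"),
            rng_seed=rng_seed,
        )
        return CMLBranch(cfg)
    if branch == "dl":
        cfg = convlstm.TrainConfig(
            learning_rate=opts.get("learning_rate", 0.001),
            epochs=opts.get("epochs", 500),
            batch_size=opts.get("batch_size", 64),
            rng_seed=rng_seed,
        )
        spec_kwargs = {
            k: opts[k]
            for k in ("dense_width", "dropout_rate", "lstm_cells")
            if k in opts
        }
        return DLBranch(cfg, spec_kwargs)
    return branch  # caller-supplied branch object


def cross_validate(
    reps: list[Repetition],
    placements,
    branch,
    folds: FoldAssignment,
    rng_seed: int = 0,
    branch_options: dict | None = None,
    eval_folds: list[int] | None = None,
    labels_override: np.ndarray | None = None,
) -> ClassificationReport:
    """Train on 9 folds, predict the held-out fold, pool predictions.

    ``branch`` is "cml", "dl", or an object exposing
    ``fit(reps, placements)`` / ``predict(reps) -> class indices``.
    ``eval_folds`` restricts which folds are held out (all by default);
    the pooled confusion matrix covers the evaluated folds only.
    ``labels_override`` substitutes the training/evaluation labels
    (integer class indices) — used for permutation-null checks.
    """
    missing = [r.subject_id for r in reps if r.subject_id not in folds]
    if missing:
        raise ValueError(f"subjects without fold assignment: {sorted(set(missing))}")
    y_all = (
        np.array([FORM_ORDER.index(r.form) for r in reps])
        if labels_override is None
        else np.asarray(labels_override, dtype=int)
    )
    if labels_override is not None:
        reps = [
            Repetition(r.subject_id, FORM_ORDER[y_all[i]], r.matrices, r.rep_index)
            for i, r in enumerate(reps)
        ]

    fold_ids = sorted(set(folds.values()))
    if eval_folds is None:
        eval_folds = fold_ids
    n_classes = len(FORM_ORDER)
    cm = np.zeros((n_classes, n_classes), dtype=int)
    for fi, fold in enumerate(eval_folds):
        train_idx = [i for i, r in enumerate(reps) if folds[r.subject_id] != fold]
        test_idx = [i for i, r in enumerate(reps) if folds[r.subject_id] == fold]
        if not test_idx:
            continue
        train_reps = [reps[i] for i in train_idx]
        if len({r.form for r in train_reps}) < n_classes:
            raise ValueError(f"training split for fold {fold} is missing a class")
        model = _make_branch(branch, rng_seed + 1000 * fi, branch_options)
        model.fit(train_reps, list(placements))
        pred = np.asarray(model.predict([reps[i] for i in test_idx]))
        for i, p in zip(test_idx, pred):
            cm[y_all[i], int(p)] += 1
    acc, sens, spec = metrics_from_confusion(cm)
    name = getattr(branch, "name", str(branch).upper())
    return ClassificationReport(
        placement_combination=tuple(placements),
        branch=name,
        confusion=cm,
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        n_folds_evaluated=len(eval_folds),
    )


def run_experiment_matrix(
    reps: list[Repetition],
    folds: FoldAssignment,
    rng_seed: int = 0,
    branch_options: dict | None = None,
    combinations=COMBINATIONS,
    branches=("cml", "dl"),
) -> list[ClassificationReport]:
    """Both branches over the placement combinations: 14 reports by default.

    ``branch_options`` maps branch name -> option dict (see
    :func:`cross_validate`).
    """
    opts = branch_options or {}
    reports = []
    for combo in combinations:
        for branch in branches:
            reports.append(
                cross_validate(
                    reps,
                    list(combo),
                    branch,
                    folds,
                    rng_seed=rng_seed,
                    branch_options=opts.get(branch),
                )
            )
    return reports


def reports_to_frame(reports: list[ClassificationReport]) -> pd.DataFrame:
    """Summary table (one row per report) mirroring the study's layout."""
    rows = []
    for r in reports:
        rows.append(
            {
                "n_imus": len(r.placement_combination),
                "placements": "+".join(p.value for p in r.placement_combination),
                "branch": r.branch,
                "accuracy": round(r.accuracy, 1),
                "sensitivity": round(r.sensitivity, 1),
                "specificity": round(r.specificity, 1),
                "n_pooled": r.n_total,
            }
        )
    return pd.DataFrame(rows)


def write_reports(
    reports: list[ClassificationReport], out_dir: str | Path
) -> None:
    """Write the summary CSV and one confusion-matrix CSV per report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reports_to_frame(reports).to_csv(out_dir / "report_summary.csv", index=False)
    labels = [f.value for f in FORM_ORDER]
    for r in reports:
        tag = "_".join(p.value for p in r.placement_combination)
        pd.DataFrame(r.confusion, index=labels, columns=labels).to_csv(
            out_dir / f"confusion_{r.branch}_{tag}.csv"
        )
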