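"""Conventional-machine-learning branch: statistical features + bagged trees.

Per sensor axis, 11 summary statistics are computed over the 40
resampled time points of a repetition — mean, median, max, min,
standard deviation, root mean square, range, 25th percentile, 75th
percentile, skewness, and kurtosis — giving 66 features per placement
(11 x 6 axes).  Multi-placement vectors concatenate sites in the fixed
order lumbar, right thigh, right calf, left thigh, left calf.

Moments use population (n) denominators; skewness is m3 / m2^1.5 and
kurtosis is excess (m4 / m2^2 - 3), both defined as 0 on a
zero-variance axis so constant channels never poison training.
Percentiles interpolate linearly between order statistics.

The classifier is a bagged decision-tree ensemble (random forest) with
per-split feature subsampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .core import AXIS_NAMES, FORM_ORDER, PLACEMENT_ORDER, SensorPlacement
from .segment import Repetition

__all__ = [
    "STAT_NAMES",
    "ForestConfig",
    "axis_statistics",
    "extract_features",
    "feature_names",
    "feature_table",
    "train_forest",
    "predict_forest",
]

#: Fixed statistic order within each axis block.
STAT_NAMES = (
    "mean",
    "median",
    "max",
    "min",
    "std",
    "rms",
    "range",
    "p25",
    "p75",
    "skewness",
    "kurtosis",
)


@dataclass(frozen=True)
class ForestConfig:
    """Random-forest hyperparameters (defaults: 500 trees, unlimited depth)."""

    n_trees: int = 500
    max_depth: int | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


def axis_statistics(x: np.ndarray) -> np.ndarray:
    """The 11 statistics of one axis, in :data:`STAT_NAMES` order."""
    x = np.asarray(x, dtype=float)
    sd = np.std(x)  # population denominator
    if sd == 0.0:
        skew = kurt = 0.0
    else:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, fisher=True, bias=True))
    return np.array(
        [
            np.mean(x),
            np.median(x),
            np.max(x),
            np.min(x),
            sd,
            np.sqrt(np.mean(x**2)),
            np.max(x) - np.min(x),
            np.percentile(x, 25),
            np.percentile(x, 75),
            skew,
            kurt,
        ]
    )


def _active_placements(
    rep: Repetition, placements: list[SensorPlacement] | None
) -> list[SensorPlacement]:
    if placements is None:
        return [p for p in PLACEMENT_ORDER if p in rep.matrices]
    return [p for p in PLACEMENT_ORDER if p in placements]


def extract_features(
    rep: Repetition, placements: list[SensorPlacement] | None = None
) -> np.ndarray:
    """Feature vector of one repetition: 66 values per active placement.

    Axis-major order (ax..gz), 11 statistics per axis; placements
    concatenated in fixed site order.
    """
    out = []
    for placement in _active_placements(rep, placements):
        mat = rep.matrices[placement]
        if mat.shape[0] != len(AXIS_NAMES):
            raise ValueError(
                f"expected {len(AXIS_NAMES)} axis rows, got {mat.shape[0]}"
            )
        for axis_row in mat:
            out.append(axis_statistics(axis_row))
    return np.concatenate(out)


def feature_names(placements: list[SensorPlacement]) -> list[str]:
    """Column names ``<site>_<axis>_<stat>`` matching extract_features."""
    return [
        f"{p.value}_{axis}_{stat}"
        for p in PLACEMENT_ORDER
        if p in placements
        for axis in AXIS_NAMES
        for stat in STAT_NAMES
    ]


def feature_table(
    reps: list[Repetition], placements: list[SensorPlacement] | None = None
) -> pd.DataFrame:
    """Feature matrix for a list of repetitions, with label metadata."""
    if placements is None:
        placements = [p for p in PLACEMENT_ORDER if p in reps[0].matrices]
    rows = [extract_features(rep, placements) for rep in reps]
    df = pd.DataFrame(np.vstack(rows), columns=feature_names(placements))
    df.insert(0, "subject", [rep.subject_id for rep in reps])
    df.insert(1, "form", [rep.form.value for rep in reps])
    df.insert(2, "rep_index", [rep.rep_index for rep in reps])
    return df


def train_forest(
    X: np.ndarray, y: np.ndarray, cfg: ForestConfig = ForestConfig()
) -> RandomForestClassifier:
    """Fit the bagged decision-tree ensemble.

    ``y`` holds form labels (strings or SquatForm values).  Raises on a
    single-class training set.
    """
    y_arr = np.asarray(y).ravel()
    if np.issubdtype(y_arr.dtype, np.integer):
        y = np.asarray([FORM_ORDER[int(v)].value for v in y_arr])
    else:
        y = np.asarray([v.value if hasattr(v, "value") else v for v in y_arr])
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain at least 2 classes")
    model = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_depth=cfg.max_depth,
        random_state=cfg.rng_seed,
        bootstrap=True,
    )
    model.fit(np.asarray(X, dtype=float), y)
    return model


def predict_forest(model: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Class-probability matrix over the six forms in canonical order.

    Rows sum to 1; columns follow :data:`squatform.core.FORM_ORDER`.
    Forms absent from training get probability 0.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features_in_:
        raise ValueError(
            f"feature length {X.shape[1]} != model's {model.n_features_in_}"
        )
    proba = model.predict_proba(X)
    out = np.zeros((X.shape[0], len(FORM_ORDER)))
    col = {f.value: i for i, f in enumerate(FORM_ORDER)}
    for j, cls in enumerate(model.classes_):
        out[:, col[cls]] = proba[:, j]
    return out
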