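"""Shared domain types and conventions for squat-form classification.

Coordinate convention (used by every module; defined only here)
---------------------------------------------------------------
Each body-worn sensor has a right-handed segment frame:

* ``x`` — anterior (points forward out of the segment),
* ``y`` — lateral-left,
* ``z`` — superior (along the segment, toward the head in standing).

The *roll* angle of a segment is its rotation about the anterior ``x``
axis.  Sensors are mounted so that the dominant sagittal-plane squat
motion (thigh inclining as the knee flexes) appears on this axis: at
upright standing gravity lies along ``+z`` and roll is 0 deg; as the
segment inclines, gravity rotates within the ``y``–``z`` plane and the
accelerometer-only roll estimate is ``atan2(a_y, a_z)``.  Frontal-plane
knee deviation (valgus/varus) is a smaller rotation about ``y`` and
shows up on ``a_x`` and the ``y`` gyroscope channel.

Axis row order for all 6xT matrices is ``ax, ay, az, gx, gy, gz``
(acceleration in g, angular rate in deg/s).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SquatForm",
    "SensorPlacement",
    "FORM_ORDER",
    "PLACEMENT_ORDER",
    "AXIS_NAMES",
    "ACCEL_RANGE_G",
    "GYRO_RANGE_DPS",
    "SensorStream",
    "Trial",
]

#: Accelerometer full-scale range, in g.
ACCEL_RANGE_G = 2.0
#: Gyroscope full-scale range, in deg/s.
GYRO_RANGE_DPS = 500.0

#: Row order of every 6xT axis matrix.
AXIS_NAMES = ("ax", "ay", "az", "gx", "gy", "gz")


class SquatForm(enum.Enum):
    """The six squat forms: one acceptable, five aberrant.

    ACC acceptable squat; AK anterior knee (knees ahead of toes);
    KVG knee valgus (knees inward); KVR knee varus (knees outward);
    HS half squat (insufficient depth); BO bent over (excessive
    hip/torso flexion).
    """

    ACC = "ACC"
    AK = "AK"
    KVG = "KVG"
    KVR = "KVR"
    HS = "HS"
    BO = "BO"


#: Canonical class order for labels, confusion-matrix rows and columns.
FORM_ORDER = (
    SquatForm.ACC,
    SquatForm.AK,
    SquatForm.KVG,
    SquatForm.KVR,
    SquatForm.HS,
    SquatForm.BO,
)


class SensorPlacement(enum.Enum):
    """The five sensor sites used in the placement-combination study."""

    LUMBAR = "lumbar"
    RIGHT_THIGH = "right_thigh"
    RIGHT_CALF = "right_calf"
    LEFT_THIGH = "left_thigh"
    LEFT_CALF = "left_calf"


#: Fixed site order for multi-sensor stacking/concatenation.
PLACEMENT_ORDER = (
    SensorPlacement.LUMBAR,
    SensorPlacement.RIGHT_THIGH,
    SensorPlacement.RIGHT_CALF,
    SensorPlacement.LEFT_THIGH,
    SensorPlacement.LEFT_CALF,
)


@dataclass
class SensorStream:
    """Time series from one 6-axis inertial sensor at one placement.

    ``accel`` is T x 3 in g, ``gyro`` is T x 3 in deg/s, columns in the
    (x, y, z) order of the segment frame documented in this module.
    """

    placement: SensorPlacement
    sample_rate: float
    accel: np.ndarray
    gyro: np.ndarray

    def __post_init__(self) -> None:
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.accel.ndim != 2 or self.accel.shape[1] != 3:
            raise ValueError("accel must be T x 3")
        if self.gyro.shape != self.accel.shape:
            raise ValueError("accel and gyro must have identical shape")

    def __len__(self) -> int:
        return self.accel.shape[0]

    def as_matrix(self) -> np.ndarray:
        """Return the 6 x T axis matrix (rows ax, ay, az, gx, gy, gz)."""
        return np.vstack([self.accel.T, self.gyro.T])


@dataclass
class Trial:
    """One trial: six consecutive repetitions of a single squat form.

    ``true_boundaries`` (present for synthetic trials) are half-open
    ``[start, end)`` sample-index pairs, one per repetition.
    """

    subject_id: int
    form: SquatForm
    streams: dict[SensorPlacement, SensorStream]
    true_boundaries: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.streams.values()}
        if len(lengths) > 1:
            raise ValueError("all streams in a trial must have equal length")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.streams.values())))

    @property
    def sample_rate(self) -> float:
        return next(iter(self.streams.values())).sample_rate
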