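"""Repetition segmentation via the analytic signal of the thigh roll angle.

The pipeline delimits the six repetitions of a trial on a single
reference channel — the roll angle of the right thigh — and applies the
same sample windows to every synchronously recorded sensor, so that a
repetition's start and end coincide across placements.  Each extracted
segment is then resampled to a fixed 40 time points per axis, giving
the 6 x 40 matrices consumed by both classification branches.

Boundary detection uses the Hilbert transform: the mean-subtracted roll
series is lifted to its analytic signal, the instantaneous phase is
unwrapped, and repetition boundaries are placed where the phase crosses
``phi0 + 2*pi*k``.  The phase origin ``phi0`` is anchored at the first
prominent minimum of the envelope-weighted signal, which for a flexion
cycle (angle rising from and returning to standing) sits at a
repetition boundary.  The rule is parameter-free and exact for
sinusoid-like cycles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, hilbert, lfilter, resample

from .core import (
    AXIS_NAMES,
    PLACEMENT_ORDER,
    SensorPlacement,
    SensorStream,
    SquatForm,
    Trial,
)

__all__ = [
    "RollAngleSeries",
    "RepetitionWindow",
    "Repetition",
    "InsufficientCyclesError",
    "compute_roll_angle",
    "detect_repetition_windows",
    "extract_repetitions",
    "segment_trial",
    "segment_dataset",
    "write_repetition_archive",
    "read_repetition_archive",
]

#: Complementary-filter gyro weight (per-sample).  High enough to track
#: fast motion from the gyroscope, low enough that the accelerometer
#: pins down the long-run gravity reference.
DEFAULT_ALPHA = 0.98

#: Number of resampled time points per repetition.
DEFAULT_OUT_LEN = 40


@dataclass
class RollAngleSeries:
    """Roll angle (degrees) over time for one stream."""

    sample_rate: float
    values: np.ndarray


@dataclass(frozen=True)
class RepetitionWindow:
    """Half-open sample-index window ``[start, end)``."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("window must satisfy 0 <= start < end")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Repetition:
    """One repetition: a 6 x out_len matrix per placement.

    Rows follow :data:`squatform.core.AXIS_NAMES`; all placements in a
    repetition come from the same source window (synchronized sensors).
    """

    subject_id: int
    form: SquatForm
    matrices: dict[SensorPlacement, np.ndarray]
    rep_index: int = 0

    def stacked(self, placements: list[SensorPlacement] | None = None) -> np.ndarray:
        """Row-stack the per-placement matrices in fixed site order."""
        if placements is None:
            placements = [p for p in PLACEMENT_ORDER if p in self.matrices]
        return np.vstack([self.matrices[p] for p in placements])


class InsufficientCyclesError(ValueError):
    """Raised when a series contains fewer full cycles than expected."""

    def __init__(self, expected: int, found: int):
        super().__init__(
            f"insufficient cycles: expected {expected}, found {found}"
        )
        self.expected = expected
        self.found = found


def compute_roll_angle(
    stream: SensorStream, alpha: float = DEFAULT_ALPHA
) -> RollAngleSeries:
    """Estimate the roll angle by complementary-filter sensor fusion.

    Fuses the integrated x-gyroscope rate with the accelerometer tilt
    ``atan2(a_y, a_z)``::

        angle[t] = alpha * (angle[t-1] + gx[t] * dt)
                   + (1 - alpha) * atan2(ay[t], az[t])

    with ``angle[0]`` taken from the accelerometer alone.  Output in
    degrees.
    """
    if len(stream) < 2:
        raise ValueError("stream must have at least 2 samples")
    dt = 1.0 / stream.sample_rate
    acc_roll = np.degrees(np.arctan2(stream.accel[:, 1], stream.accel[:, 2]))
    gx = stream.gyro[:, 0]
    # Recurrence y[t] = alpha*y[t-1] + u[t] as an IIR filter, with
    # u[t] = alpha*gx[t]*dt + (1-alpha)*acc_roll[t].
    u = alpha * gx * dt + (1.0 - alpha) * acc_roll
    y0 = acc_roll[0]
    y, _ = lfilter([1.0], [1.0, -alpha], u[1:], zi=np.array([alpha * y0]))
    values = np.concatenate([[y0], y])
    return RollAngleSeries(sample_rate=stream.sample_rate, values=values)


def _phase_crossing_times(phase: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """Sub-sample times where an increasing phase crosses each level."""
    mono = np.maximum.accumulate(phase)  # guard small noise reversals
    idx = np.searchsorted(mono, levels)
    times = np.empty(len(levels))
    for i, (lvl, j) in enumerate(zip(levels, idx)):
        if j <= 0:
            times[i] = 0.0
        elif j >= len(mono):
            times[i] = len(mono) - 1
        else:
            lo, hi = mono[j - 1], mono[j]
            frac = 0.0 if hi == lo else (lvl - lo) / (hi - lo)
            times[i] = (j - 1) + frac
    return times


def detect_repetition_windows(
    roll: RollAngleSeries, expected_count: int = 6
) -> list[RepetitionWindow]:
    """Delimit repetitions from the unwrapped analytic-signal phase.

    Returns exactly ``expected_count`` disjoint, time-ordered half-open
    windows.  Raises :class:`InsufficientCyclesError` when fewer full
    phase cycles are present.
    """
    if expected_count < 1:
        raise ValueError("expected_count must be >= 1")
    x = np.asarray(roll.values, dtype=float)
    n = len(x)
    x = x - x.mean()
    if n < 4 or np.std(x) == 0.0:
        raise InsufficientCyclesError(expected_count, 0)

    analytic = hilbert(x)
    phase = np.unwrap(np.angle(analytic))
    envelope = np.abs(analytic)

    # Phase origin: first prominent minimum of the envelope-weighted
    # signal (for a flexion cycle the minima are the rep boundaries).
    weighted = x * envelope / (envelope.max() + np.finfo(float).tiny)
    minima, _ = find_peaks(-weighted, prominence=0.5 * np.std(weighted))
    t0 = int(minima[0]) if len(minima) else int(np.argmin(weighted))
    phi0 = phase[t0]

    total_span = phase[-1] - phase[0]
    # Integer phase offsets k whose crossing phi0 + 2*pi*k lies inside
    # the recorded span; allow a quarter-cycle of slack at each edge so
    # a boundary sitting exactly on the first/last sample is kept
    # (clamped to the edge).
    slack = np.pi / 2.0
    k_lo = int(np.ceil((phase[0] - phi0 - slack) / (2.0 * np.pi)))
    k_hi = int(np.floor((phase[-1] - phi0 + slack) / (2.0 * np.pi)))
    ks = np.arange(k_lo, k_hi + 1)
    n_boundaries = expected_count + 1
    if len(ks) < n_boundaries:
        found = max(0, len(ks) - 1)
        raise InsufficientCyclesError(expected_count, found)
    if len(ks) > n_boundaries:
        # More cycles than expected: keep the consecutive run whose span
        # carries the most signal energy (envelope mass).
        levels = phi0 + 2.0 * np.pi * ks
        times = _phase_crossing_times(phase, levels)
        cum = np.concatenate([[0.0], np.cumsum(envelope**2)])
        best, best_score = 0, -np.inf
        for s in range(len(ks) - n_boundaries + 1):
            a = int(round(times[s]))
            b = int(round(times[s + n_boundaries - 1]))
            score = cum[min(b + 1, n)] - cum[min(a, n)]
            if score > best_score:
                best, best_score = s, score
        ks = ks[best : best + n_boundaries]

    levels = phi0 + 2.0 * np.pi * ks
    times = _phase_crossing_times(phase, levels)
    bounds = np.clip(np.rint(times).astype(int), 0, n)
    # Enforce strict ordering after rounding.
    for i in range(1, len(bounds)):
        if bounds[i] <= bounds[i - 1]:
            bounds[i] = bounds[i - 1] + 1
    if bounds[-1] > n:
        raise InsufficientCyclesError(expected_count, expected_count - 1)
    return [
        RepetitionWindow(int(bounds[i]), int(bounds[i + 1]))
        for i in range(expected_count)
    ]


def _resample_segment(seg: np.ndarray, out_len: int, method: str) -> np.ndarray:
    """Resample each row of a (rows, n) segment to out_len points."""
    if method == "fourier":
        return resample(seg, out_len, axis=1)
    if method == "linear":
        xp = np.linspace(0.0, 1.0, seg.shape[1])
        xq = np.linspace(0.0, 1.0, out_len)
        return np.vstack([np.interp(xq, xp, row) for row in seg])
    raise ValueError(f"unknown resampling method: {method!r}")


def extract_repetitions(
    trial: Trial,
    windows: list[RepetitionWindow],
    out_len: int = DEFAULT_OUT_LEN,
    method: str = "fourier",
) -> list[Repetition]:
    """Cut every placement's stream at the shared windows and resample.

    The same sample windows are applied to all placements (the sensors
    record simultaneously), and each axis segment is resampled to
    ``out_len`` points — Fourier-method by default, linear by config.
    """
    n = trial.n_samples
    reps: list[Repetition] = []
    for i, w in enumerate(windows):
        if w.end > n:
            raise ValueError(f"window {w} exceeds stream length {n}")
        matrices = {}
        for placement, stream in trial.streams.items():
            seg = stream.as_matrix()[:, w.start : w.end]
            matrices[placement] = _resample_segment(seg, out_len, method)
        reps.append(
            Repetition(
                subject_id=trial.subject_id,
                form=trial.form,
                matrices=matrices,
                rep_index=i,
            )
        )
    return reps


def segment_trial(
    trial: Trial,
    expected_count: int = 6,
    out_len: int = DEFAULT_OUT_LEN,
    alpha: float = DEFAULT_ALPHA,
    method: str = "fourier",
) -> list[Repetition]:
    """Full per-trial segmentation on the right-thigh roll reference."""
    if SensorPlacement.RIGHT_THIGH not in trial.streams:
        raise ValueError("trial lacks the right-thigh reference sensor")
    roll = compute_roll_angle(trial.streams[SensorPlacement.RIGHT_THIGH], alpha)
    windows = detect_repetition_windows(roll, expected_count)
    return extract_repetitions(trial, windows, out_len=out_len, method=method)


def segment_dataset(
    trials: list[Trial],
    expected_count: int = 6,
    out_len: int = DEFAULT_OUT_LEN,
) -> list[Repetition]:
    """Segment every trial; repetition count = trials x expected_count."""
    reps: list[Repetition] = []
    for trial in trials:
        reps.extend(segment_trial(trial, expected_count, out_len))
    return reps


# ---------------------------------------------------------------------------
# Repetition archive: one CSV table per placement.

def write_repetition_archive(
    reps: list[Repetition], out_dir: str | Path
) -> None:
    """Write one CSV per placement: subject, form, rep_index, axis, s0..s39."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_placement: dict[SensorPlacement, list[dict]] = {}
    for rep in reps:
        for placement, mat in rep.matrices.items():
            rows = by_placement.setdefault(placement, [])
            for axis_i, axis in enumerate(AXIS_NAMES):
                row = {
                    "subject": rep.subject_id,
                    "form": rep.form.value,
                    "rep_index": rep.rep_index,
                    "axis": axis,
                }
                row.update(
                    {f"s{j}": mat[axis_i, j] for j in range(mat.shape[1])}
                )
                rows.append(row)
    for placement, rows in by_placement.items():
        pd.DataFrame(rows).to_csv(
            out_dir / f"repetitions_{placement.value}.csv",
            index=False,
            float_format="%.6g",
        )


def read_repetition_archive(in_dir: str | Path) -> list[Repetition]:
    """Read an archive written by :func:`write_repetition_archive`."""
    in_dir = Path(in_dir)
    frames = {}
    for placement in PLACEMENT_ORDER:
        f = in_dir / f"repetitions_{placement.value}.csv"
        if f.exists():
            frames[placement] = pd.read_csv(f)
    if not frames:
        raise FileNotFoundError(f"no repetition tables found in {in_dir}")
    reps: dict[tuple, Repetition] = {}
    for placement, df in frames.items():
        sample_cols = [c for c in df.columns if c[0] == "s" and c[1:].isdigit()]
        sample_cols.sort(key=lambda c: int(c[1:]))
        axis_order = {a: i for i, a in enumerate(AXIS_NAMES)}
        for key, group in df.groupby(["subject", "form", "rep_index"]):
            subject, form, rep_index = key
            group = group.sort_values("axis", key=lambda s: s.map(axis_order))
            mat = group[sample_cols].to_numpy()
            rep = reps.setdefault(
                key,
                Repetition(
                    subject_id=int(subject),
                    form=SquatForm(form),
                    matrices={},
                    rep_index=int(rep_index),
                ),
            )
            rep.matrices[placement] = mat
    ordered = sorted(reps.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2]))
    return [rep for _, rep in ordered]
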