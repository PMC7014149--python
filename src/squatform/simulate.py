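"""Synthetic generator for labeled multi-sensor squat trials.

Emulates the study design the analysis assumes: each trial is six
consecutive repetitions (nominal 3 s each) of one of six squat forms,
recorded by up to five 6-axis inertial sensors (3-axis accelerometer
±2 g, 3-axis gyroscope ±500 deg/s).  The real cohort is not available,
so this module provides a kinematic forward model with ground-truth
repetition boundaries and labels for testing the downstream pipeline.

Kinematic model
---------------
A planar three-link sagittal chain (trunk - thigh - calf) driven by a
raised-cosine flexion cycle ``c(t) = (1 - cos(2*pi*t/T)) / 2`` per
repetition, plus an additive frontal-plane channel on thigh and calf
for the valgus/varus forms.  Per form, peak joint angles (knee flexion,
hip flexion, trunk pitch, signed frontal deviation, anterior-knee
proxy) define segment orientations:

* lumbar sagittal angle  = trunk pitch peak * c(t)
* thigh  sagittal angle  = (hip peak - trunk peak + 0.3 * AK proxy) * c(t)
* calf   sagittal angle  = (base shank pitch + AK proxy) * c(t)
* thigh/calf frontal angle = ±deviation * c(t)  (mirrored left/right)

The accelerometer reads the gravity direction rotated into the segment
frame; the gyroscope reads the analytic time derivative of the segment
Euler angles.  Both get additive Gaussian noise and are clipped at the
sensor ranges.  The thigh sagittal angle is what the segmentation
stage's roll estimator must recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .core import (
    ACCEL_RANGE_G,
    AXIS_NAMES,
    FORM_ORDER,
    GYRO_RANGE_DPS,
    PLACEMENT_ORDER,
    SensorPlacement,
    SensorStream,
    SquatForm,
    Trial,
)

__all__ = [
    "SubjectParams",
    "KinematicProfile",
    "FORM_PROFILES",
    "derive_seed",
    "generate_subject",
    "generate_trial",
    "generate_dataset",
    "ground_truth_thigh_roll",
    "write_trial_csv",
    "read_trial_csv",
]

#: Default repetition duration in seconds.
REP_DURATION_S = 3.0
#: Default repetitions per trial.
REPS_PER_TRIAL = 6
#: Default working sample rate, Hz.  The downstream stages are
#: rate-agnostic; 100 Hz keeps simulated trials small.
DEFAULT_SAMPLE_RATE = 100.0

#: Base shank (calf) sagittal pitch peak in degrees, before the
#: anterior-knee proxy is added.
CALF_BASE_PITCH_DEG = 15.0
#: Fraction of the anterior-knee proxy that couples into the thigh
#: sagittal angle (closed kinetic chain: distal deviations shift the
#: proximal segment too).
AK_THIGH_COUPLING = 0.3


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject variability parameters.

    depth_scale multiplies every peak joint angle (a deep vs shallow
    mover); tempo_jitter is the half-width of the uniform per-repetition
    duration perturbation, as a fraction of the 3 s nominal duration;
    noise standard deviations are in sensor units (g, deg/s).
    """

    subject_id: int
    depth_scale: float
    tempo_jitter: float
    noise_sd_accel: float
    noise_sd_gyro: float
    rng_seed: int

    def __post_init__(self) -> None:
        if self.depth_scale <= 0:
            raise ValueError("depth_scale must be positive")
        if abs(self.tempo_jitter) >= 0.3:
            raise ValueError("|tempo_jitter| must be < 0.3")
        if self.noise_sd_accel < 0 or self.noise_sd_gyro < 0:
            raise ValueError("noise standard deviations must be >= 0")


@dataclass(frozen=True)
class KinematicProfile:
    """Peak joint angles (degrees) and timing defining one squat form.

    ``frontal_deviation_deg`` is signed: positive = valgus (knees
    inward), negative = varus.  ``anterior_knee_deg`` is the extra
    shank pitch produced by the knees travelling ahead of the toes; it
    grows quadratically with the flexion cycle (the knees drift
    forward progressively as depth increases).  ``descent_fraction``
    is the share of the repetition spent descending: 0.5 is a
    symmetric cycle; the bent-over form descends slowly, torso-first,
    and rises faster.
    """

    knee_flexion_deg: float
    hip_flexion_deg: float
    trunk_pitch_deg: float
    frontal_deviation_deg: float
    anterior_knee_deg: float
    descent_fraction: float = 0.5


#: Default per-form kinematic signatures.  The magnitudes and timings
#: are design values chosen to reproduce the forms' qualitative
#: descriptions (half squat shallower than acceptable, bent-over with
#: larger trunk pitch and a trunk-led slow descent, valgus/varus
#: distinguished by the sign of the frontal deviation, anterior knee
#: expressed mostly below the knee and concentrated at depth).
FORM_PROFILES: dict[SquatForm, KinematicProfile] = {
    SquatForm.ACC: KinematicProfile(100.0, 90.0, 40.0, 0.0, 0.0),
    SquatForm.AK: KinematicProfile(100.0, 90.0, 40.0, 0.0, 25.0),
    SquatForm.KVG: KinematicProfile(100.0, 90.0, 40.0, +15.0, 0.0),
    SquatForm.KVR: KinematicProfile(100.0, 90.0, 40.0, -15.0, 0.0),
    SquatForm.HS: KinematicProfile(50.0, 45.0, 25.0, 0.0, 0.0),
    SquatForm.BO: KinematicProfile(100.0, 130.0, 70.0, 0.0, 0.0, 0.60),
}


def derive_seed(*keys: int) -> int:
    """Derive a child seed from integer keys (splitmix64-style).

    Deterministic, stateless, and well-mixed, so any subject or trial
    is reproducible in isolation from the master seed.
    """
    h = np.uint64(0x9E3779B97F4A7C15)
    z = np.uint64(0)
    with np.errstate(over="ignore"):
        for k in keys:
            z = (z + np.uint64(k & 0xFFFFFFFFFFFFFFFF) + h) * np.uint64(
                0xBF58476D1CE4E5B9
            )
            z ^= z >> np.uint64(30)
            z *= np.uint64(0x94D049BB133111EB)
            z ^= z >> np.uint64(31)
    return int(z)


def generate_subject(
    subject_id: int,
    master_seed: int,
    *,
    depth_scale_sd: float = 0.1,
    tempo_jitter_max: float = 0.1,
    noise_sd_accel: float = 0.02,
    noise_sd_gyro: float = 2.0,
) -> SubjectParams:
    """Draw one subject's variability parameters.

    depth_scale ~ N(1, depth_scale_sd) truncated to [0.5, 1.5];
    tempo_jitter ~ U(-tempo_jitter_max, tempo_jitter_max).  The draw is
    a pure function of (subject_id, master_seed).
    """
    seed = derive_seed(master_seed, subject_id, 0x5B)
    rng = np.random.default_rng(seed)
    depth = float(np.clip(rng.normal(1.0, depth_scale_sd), 0.5, 1.5))
    jitter = float(rng.uniform(-tempo_jitter_max, tempo_jitter_max))
    return SubjectParams(
        subject_id=subject_id,
        depth_scale=depth,
        tempo_jitter=jitter,
        noise_sd_accel=noise_sd_accel,
        noise_sd_gyro=noise_sd_gyro,
        rng_seed=seed,
    )


def _segment_angles(
    profile: KinematicProfile, placement: SensorPlacement, depth_scale: float
) -> tuple[float, float, float]:
    """Per-placement angle coefficients, scaled by depth.

    Returns ``(linear, quadratic, frontal)`` peak angles in degrees:
    the sagittal angle over time is ``linear*c(t) + quadratic*c(t)^2``
    and the frontal angle is ``frontal*c(t)`` (quadratic terms carry
    the anterior-knee drift, which concentrates at depth).
    """
    if placement is SensorPlacement.LUMBAR:
        lin, quad, frontal = profile.trunk_pitch_deg, 0.0, 0.0
    elif placement in (SensorPlacement.RIGHT_THIGH, SensorPlacement.LEFT_THIGH):
        lin = profile.hip_flexion_deg - profile.trunk_pitch_deg
        quad = AK_THIGH_COUPLING * profile.anterior_knee_deg
        frontal = profile.frontal_deviation_deg
    else:  # calves
        lin = CALF_BASE_PITCH_DEG
        quad = profile.anterior_knee_deg
        frontal = profile.frontal_deviation_deg
    if placement in (SensorPlacement.LEFT_THIGH, SensorPlacement.LEFT_CALF):
        frontal = -frontal  # mirror: "both knees inward" is symmetric
    return lin * depth_scale, quad * depth_scale, frontal * depth_scale


def _flexion_cycle(
    rep_samples: np.ndarray, sample_rate: float, descent_fraction: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Concatenated flexion cycle c(t) in [0, 1] and dc/dt for all reps.

    Each repetition is a raised-cosine descent over the first
    ``descent_fraction`` of its duration and a raised-cosine ascent
    over the remainder; at 0.5 this is the symmetric cycle
    ``(1 - cos(2*pi*tau))/2``.  rep_samples holds the integer length
    of each repetition; consecutive repetitions join continuously at
    c = 0.  dc/dt is the analytic derivative in 1/s.
    """
    eta = descent_fraction
    cs, dcs = [], []
    for n in rep_samples:
        tau = np.arange(n) / n  # cycle fraction in [0, 1)
        T = n / sample_rate  # repetition duration in s
        down = tau < eta
        c = np.where(
            down,
            0.5 * (1.0 - np.cos(np.pi * tau / eta)),
            0.5 * (1.0 + np.cos(np.pi * (tau - eta) / (1.0 - eta))),
        )
        dc = np.where(
            down,
            0.5 * np.pi / (eta * T) * np.sin(np.pi * tau / eta),
            -0.5 * np.pi / ((1.0 - eta) * T)
            * np.sin(np.pi * (tau - eta) / (1.0 - eta)),
        )
        cs.append(c)
        dcs.append(dc)
    return np.concatenate(cs), np.concatenate(dcs)


def generate_trial(
    subject: SubjectParams,
    form: SquatForm,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    placements: set[SensorPlacement] | frozenset[SensorPlacement] | None = None,
    reps_per_trial: int = REPS_PER_TRIAL,
    rep_duration_s: float = REP_DURATION_S,
) -> Trial:
    """Simulate one trial of ``reps_per_trial`` repetitions of ``form``.

    Raises ValueError for an empty placement set or a sample rate below
    20 Hz.  Deterministic given the subject's derived seed and form.
    """
    if placements is None:
        placements = set(PLACEMENT_ORDER)
    if not placements:
        raise ValueError("placements is empty: nothing to simulate")
    if sample_rate < 20:
        raise ValueError("sample_rate must be >= 20 Hz")

    form_index = FORM_ORDER.index(form)
    rng = np.random.default_rng(derive_seed(subject.rng_seed, form_index, 0xA7))

    # Per-repetition durations: 3 s * (1 + U(-|tempo_jitter|, +|tempo_jitter|)).
    half = abs(subject.tempo_jitter)
    factors = 1.0 + rng.uniform(-half, half, size=reps_per_trial)
    rep_samples = np.maximum(
        4, np.rint(rep_duration_s * factors * sample_rate).astype(int)
    )
    starts = np.concatenate([[0], np.cumsum(rep_samples)])
    boundaries = [(int(starts[i]), int(starts[i + 1])) for i in range(reps_per_trial)]

    profile = FORM_PROFILES[form]
    c, dc = _flexion_cycle(rep_samples, sample_rate, profile.descent_fraction)

    streams: dict[SensorPlacement, SensorStream] = {}
    for placement in PLACEMENT_ORDER:
        if placement not in placements:
            continue
        lin, quad, frontal_peak = _segment_angles(
            profile, placement, subject.depth_scale
        )
        phi = lin * c + quad * c**2  # deg, rotation about x (sagittal "roll")
        psi = frontal_peak * c  # deg, rotation about y (frontal)
        rot = Rotation.from_euler("xy", np.column_stack([phi, psi]), degrees=True)
        accel = rot.apply(np.array([0.0, 0.0, 1.0]), inverse=True)
        gyro = np.column_stack(
            [(lin + 2.0 * quad * c) * dc, frontal_peak * dc, np.zeros_like(c)]
        )  # deg/s, analytic Euler-angle rates
        if subject.noise_sd_accel > 0:
            accel = accel + rng.normal(0.0, subject.noise_sd_accel, accel.shape)
        if subject.noise_sd_gyro > 0:
            gyro = gyro + rng.normal(0.0, subject.noise_sd_gyro, gyro.shape)
        accel = np.clip(accel, -ACCEL_RANGE_G, ACCEL_RANGE_G)
        gyro = np.clip(gyro, -GYRO_RANGE_DPS, GYRO_RANGE_DPS)
        streams[placement] = SensorStream(placement, sample_rate, accel, gyro)

    return Trial(
        subject_id=subject.subject_id,
        form=form,
        streams=streams,
        true_boundaries=boundaries,
    )


def ground_truth_thigh_roll(
    subject: SubjectParams,
    form: SquatForm,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    reps_per_trial: int = REPS_PER_TRIAL,
) -> np.ndarray:
    """Noise-free right-thigh sagittal angle (deg) for oracle tests.

    Reuses the trial's seeded tempo draw so the returned series aligns
    sample-for-sample with generate_trial's output.
    """
    form_index = FORM_ORDER.index(form)
    rng = np.random.default_rng(derive_seed(subject.rng_seed, form_index, 0xA7))
    half = abs(subject.tempo_jitter)
    factors = 1.0 + rng.uniform(-half, half, size=reps_per_trial)
    rep_samples = np.maximum(
        4, np.rint(REP_DURATION_S * factors * sample_rate).astype(int)
    )
    profile = FORM_PROFILES[form]
    c, _ = _flexion_cycle(rep_samples, sample_rate, profile.descent_fraction)
    lin, quad, _ = _segment_angles(
        profile, SensorPlacement.RIGHT_THIGH, subject.depth_scale
    )
    return lin * c + quad * c**2


def generate_dataset(
    n_subjects: int,
    forms: list[SquatForm] | tuple[SquatForm, ...] = FORM_ORDER,
    reps_per_trial: int = REPS_PER_TRIAL,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    master_seed: int = 0,
    placements: set[SensorPlacement] | None = None,
    **subject_kwargs,
) -> list[Trial]:
    """Simulate the full study design: one trial per (subject, form).

    Form order is randomized per subject with a seeded RNG, mirroring
    the protocol in which participants performed the forms in random
    order.  Total ground-truth repetitions per placement equal
    ``n_subjects * len(forms) * reps_per_trial``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    trials: list[Trial] = []
    for sid in range(1, n_subjects + 1):
        subject = generate_subject(sid, master_seed, **subject_kwargs)
        order_rng = np.random.default_rng(derive_seed(master_seed, sid, 0xC3))
        order = order_rng.permutation(len(forms))
        for idx in order:
            trials.append(
                generate_trial(
                    subject,
                    forms[idx],
                    sample_rate=sample_rate,
                    placements=placements,
                    reps_per_trial=reps_per_trial,
                )
            )
    return trials


# ---------------------------------------------------------------------------
# Plain-text trial format: one CSV per trial plus a JSON sidecar.

def write_trial_csv(trial: Trial, path: str | Path) -> None:
    """Write a trial as CSV (columns t, <site>_ax..gz) + JSON sidecar."""
    path = Path(path)
    t = np.arange(trial.n_samples) / trial.sample_rate
    data: dict[str, np.ndarray] = {"t": t}
    for placement in PLACEMENT_ORDER:
        if placement not in trial.streams:
            continue
        stream = trial.streams[placement]
        mat = stream.as_matrix()
        for row, axis in enumerate(AXIS_NAMES):
            data[f"{placement.value}_{axis}"] = mat[row]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6g")
    meta = {
        "subject_id": trial.subject_id,
        "form": trial.form.value,
        "sample_rate": trial.sample_rate,
        "true_boundaries": [list(b) for b in trial.true_boundaries],
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_trial_csv(path: str | Path) -> Trial:
    """Read a trial written by :func:`write_trial_csv`."""
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    streams: dict[SensorPlacement, SensorStream] = {}
    for placement in PLACEMENT_ORDER:
        cols = [f"{placement.value}_{axis}" for axis in AXIS_NAMES]
        if cols[0] not in df.columns:
            continue
        mat = df[cols].to_numpy().T
        streams[placement] = SensorStream(
            placement, meta["sample_rate"], mat[:3].T, mat[3:].T
        )
    return Trial(
        subject_id=meta["subject_id"],
        form=SquatForm(meta["form"]),
        streams=streams,
        true_boundaries=[tuple(b) for b in meta["true_boundaries"]],
    )
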