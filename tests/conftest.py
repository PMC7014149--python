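import numpy as np
import pytest
from hypothesis import settings

from squatform import segment, simulate
from squatform.core import FORM_ORDER, SensorPlacement

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def noise_free_subject():
    """Deterministic subject with zero noise and zero tempo jitter."""
    return simulate.SubjectParams(
        subject_id=1,
        depth_scale=1.0,
        tempo_jitter=0.0,
        noise_sd_accel=0.0,
        noise_sd_gyro=0.0,
        rng_seed=123,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """6 subjects x 6 forms, right thigh only, segmented (216 reps)."""
    trials = simulate.generate_dataset(
        6, master_seed=11, placements={SensorPlacement.RIGHT_THIGH}
    )
    reps = segment.segment_dataset(trials)
    return trials, reps


@pytest.fixture(scope="session")
def small_multisensor_dataset():
    """4 subjects x 6 forms with all five placements, segmented."""
    trials = simulate.generate_dataset(4, master_seed=17)
    return trials, segment.segment_dataset(trials)
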