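import hypothesis
import numpy as np
import pytest

import ppgbreathe as pb
from ppgbreathe.synthetic_data import MotionBurst, SynthParams, with_bursts

hypothesis.settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("ci")

#: reduced boosting size for mechanics-only unit tests (not the study conditions)
FAST_HP = {"n_estimators": 60, "learning_rate": 0.1, "max_depth": 3, "subsample": 0.8}


@pytest.fixture(scope="session")
def study_protocol():
    """Constant-rate protocol spanning 9–18 bpm (four 60-s segments)."""
    return pb.constant_rate_protocol([9.0, 12.0, 15.0, 18.0], 60.0, name="sweep9to18")


@pytest.fixture(scope="session")
def cohort(study_protocol):
    """Ten-subject synthetic cohort at mild noise (the acceptance study conditions)."""
    return pb.generate_cohort(10, study_protocol, seed=1)


@pytest.fixture(scope="session")
def threshold(cohort):
    return pb.calibrate_cohort_threshold(cohort)


@pytest.fixture(scope="session")
def clean_table(cohort, threshold):
    return pb.featurize_cohort(cohort, threshold=threshold, window_s=20.0, slide_s=2.0)


@pytest.fixture(scope="session")
def clean_loso(clean_table):
    return pb.loso(clean_table, seed=1)


@pytest.fixture(scope="session")
def bursty_cohort(cohort):
    """Same cohort with one 6-s motion burst per subject (~10% of windows affected)."""
    rng = np.random.default_rng(123)
    return [
        with_bursts(rec, (MotionBurst(float(rng.uniform(30.0, 200.0)), 6.0, 0.5),))
        for rec in cohort
    ]


@pytest.fixture(scope="session")
def clean_recording():
    """Single noise-free, modulation-rich recording at a constant 12 bpm."""
    proto = pb.constant_rate_protocol([12.0], 120.0, name="steady12")
    params = SynthParams(
        hr_baseline=70.0,
        rsa_depth=0.08,
        am_depth=0.1,
        bw_amplitude=0.3,
        noise_sd=0.0,
        accel_noise_sd=0.0,
        seed=7,
    )
    return pb.generate_recording(proto, params)
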