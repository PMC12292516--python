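import numpy as np
import pytest
from hypothesis import settings

import somascan as sm

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")


@pytest.fixture
def manual_record():
    """The hand-traced reference subject used across the suite."""
    return sm.ManualAnthropometry(
        subject_id="ref1",
        sex=sm.Sex.female,
        age=22,
        height=171,
        weight=69.86,
        skinfold_triceps=12,
        skinfold_subscapular=14,
        skinfold_supraspinale=10,
        skinfold_medial_calf=10,
        girth_biceps=30,
        girth_calf=37,
        breadth_humerus=7,
        breadth_femur=10,
    )


@pytest.fixture
def scan_record():
    """The hand-traced male scan subject (C7 1450 mm -> height 170.045 cm)."""
    return sm.ScanAnthropometry(
        subject_id="scan1",
        sex=sm.Sex.male,
        age=24,
        weight=69.86,
        c7_height=1450,
        circ_waist=85,
        circ_hips=98,
        circ_neck=38,
        girth_biceps=30,
        girth_calf=37,
        breadth_humerus=7,
        breadth_femur=10,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort():
    """Small seeded synthetic cohort (fast enough for every test)."""
    return sm.generate_manual_cohort(sm.CohortConfig(n=24, seed=7))
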