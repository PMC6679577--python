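from datetime import datetime, timedelta

import pytest

from cprtutor.labeling import GuidelineThresholds, label_compressions
from cprtutor.simulate import SimulationParams, simulate_session


@pytest.fixture(scope="session")
def clean_session():
    """Noise-free 30 s session at the guideline sweet spot (110/55/2)."""
    params = SimulationParams(
        rate_cpm=110.0, depth_mm=55.0, release_mm=2.0, duration_s=30.0, seed=7
    )
    session, truth = simulate_session(params)
    return session, truth, params


@pytest.fixture(scope="session")
def small_cohort():
    """Three labeled jittered sessions spanning all rate/depth/release classes."""
    specs = [
        (90.0, 45.0, 2.0, True, True),
        (110.0, 55.0, 2.0, True, True),
        (130.0, 65.0, 10.0, True, True),
    ]
    labeled = []
    truths = []
    for i, (rate, depth, release, arms, weight) in enumerate(specs):
        params = SimulationParams(
            rate_cpm=rate,
            depth_mm=depth,
            release_mm=release,
            arms_locked=arms,
            body_weight=weight,
            duration_s=20.0,
            rate_jitter_cpm=1.0,
            depth_jitter_mm=1.0,
            release_jitter_mm=0.5,
            sensor_noise_sd=0.002,
            seed=100 + i,
        )
        session, truth = simulate_session(
            params,
            session_id=f"cohort-{i}",
            recording_datetime=datetime(2019, 1, 1) + timedelta(hours=i),
        )
        intervals = label_compressions(
            session.annotation_recordings[0].intervals, GuidelineThresholds()
        )
        labeled.append((session, intervals))
        truths.append(truth)
    return labeled, truths
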