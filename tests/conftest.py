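"""Shared fixtures: synthetic recordings reused across test modules."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from icpulse.synth import EpisodePlan, generate_recording

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_plan() -> EpisodePlan:
    return EpisodePlan(seed=1)


@pytest.fixture(scope="session")
def clean_plan(default_plan) -> EpisodePlan:
    """Default wave, no noise, no artifacts."""
    return replace(
        default_plan, noise_sd_icp=0.0, noise_sd_abp=0.0, noise_sd_cbfv=0.0, artifact_rate=0.0
    )


@pytest.fixture(scope="session")
def clean_recording(clean_plan):
    return generate_recording(clean_plan)


@pytest.fixture(scope="session")
def default_recording(default_plan):
    return generate_recording(default_plan)


@pytest.fixture(scope="session")
def short_clean_recording():
    """A compact clean recording (wave included) for pipeline-level tests."""
    plan = EpisodePlan(
        seed=3,
        total_duration=600.0,
        wave_start=180.0,
        wave_rise_duration=45.0,
        wave_plateau_duration=240.0,
        wave_fall_duration=45.0,
        noise_sd_icp=0.0,
        noise_sd_abp=0.0,
        noise_sd_cbfv=0.0,
        artifact_rate=0.0,
    )
    return generate_recording(plan)


def match_onsets(detected: np.ndarray, truth: np.ndarray, tol: int):
    """Greedy one-to-one matching of detected to true onsets within ``tol``."""
    used = np.zeros(detected.size, dtype=bool)
    hits = 0
    for t in truth:
        if detected.size == 0:
            break
        i = int(np.argmin(np.abs(detected - t)))
        if not used[i] and abs(int(detected[i]) - int(t)) <= tol:
            used[i] = True
            hits += 1
    false_pos = int(detected.size - used.sum())
    return hits, false_pos
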