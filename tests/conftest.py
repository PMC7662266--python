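"""Shared fixtures: small synthetic cohorts reused across the suite."""

import pytest

import shoegait as sg

#: reduced recording lengths used throughout the suite (seconds)
SHORT_DURATIONS = {
    "normal": 90.0, "unstable_left": 30.0, "unstable_right": 30.0,
    "supination": 30.0, "pronation": 30.0,
}
TINY_DURATIONS = {cls: 30.0 for cls in sg.GAIT_CLASSES}


@pytest.fixture(scope="session")
def cohort6():
    """Six-participant low-noise cohort: the separable pipeline testbed."""
    return sg.simulate_cohort(
        6, seed=1, durations_per_class=SHORT_DURATIONS, noise_scale=0.2
    )


@pytest.fixture(scope="session")
def stride_table(cohort6):
    """Retained (172-feature) stride table of the six-participant cohort."""
    segments = sg.segment_cohort(cohort6, "stride")
    full = sg.build_feature_table(segments, cohort6)
    return sg.apply_discard_rule(full)


@pytest.fixture(scope="session")
def cohort2():
    """Two-participant smoke cohort at default noise."""
    return sg.simulate_cohort(
        2, seed=3, durations_per_class=TINY_DURATIONS
    )


@pytest.fixture(scope="session")
def normal_recording():
    """One deterministic normal-gait recording with known parameters."""
    profile = sg.ParticipantProfile(
        participant_id=1, cadence=60.0, amplitude_scale=1.0,
        noise_scale=1.0, stance_factor=1.0, rng_seed=42,
    )
    return sg.simulate_recording(
        profile, sg.class_signature("normal"), duration=60.0,
        sampling_rate=100.0,
    )
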