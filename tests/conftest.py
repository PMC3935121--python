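"""Shared fixtures: small synthetic datasets and hand-built trial layouts."""

from __future__ import annotations

import numpy as np
import pytest

from irffrr.dataset import Trial, TrialDataset
from irffrr.simulate import StimulusProfile, SyntheticConfig, generate_dataset


def make_fake_dataset(
    n_sessions: int = 4,
    trials_per_session: int = 18,
    n_samples: int = 30,
    n_channels: int = 4,
    n_dofs: int = 3,
    seed: int = 0,
) -> TrialDataset:
    """Tiny hand-built dataset for exercising schedules and reports.

    Targets are a fixed noisy linear function of the inputs, so any learner
    scores sensibly; layout metadata mirrors the real protocol.
    """
    rng = np.random.default_rng(seed)
    W = rng.uniform(0.2, 1.0, size=(n_channels, n_dofs))
    sessions = []
    for s in range(1, n_sessions + 1):
        trials = []
        for t in range(1, trials_per_session + 1):
            emg = rng.uniform(0, 1, size=(n_samples, n_channels))
            force = emg @ W + rng.normal(0, 0.02, size=(n_samples, n_dofs))
            trials.append(
                Trial(
                    emg=emg,
                    force=force,
                    stimulus=np.clip(force + rng.normal(0, 0.01, force.shape), 0, None),
                    trial_index=t,
                    session_index=s,
                    day_index=(s - 1) // 2 + 1,
                )
            )
        sessions.append(trials)
    return TrialDataset(sessions=sessions, seed=seed)


@pytest.fixture(scope="session")
def fake_dataset() -> TrialDataset:
    """Standard 4 x 18 layout with tiny trials (fast harness tests)."""
    return make_fake_dataset()


@pytest.fixture(scope="session")
def short_protocol_config() -> SyntheticConfig:
    """Down-scaled protocol timing for fast end-to-end tests."""
    return SyntheticConfig(
        profile=StimulusProfile(
            plateau_durations=(0.5,), ramp_duration=0.3, rest_duration=0.8
        ),
        sessions=2,
        trials_per_session=4,
        seed=11,
    )


@pytest.fixture(scope="session")
def short_protocol_dataset(short_protocol_config) -> TrialDataset:
    return generate_dataset(short_protocol_config)
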