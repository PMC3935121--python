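"""Trial/session containers: the chronological unit of training, testing
and cross-validation.

A *trial* is one pass of sequential single-finger activations (or one grasp
repetition); a *session* is an ordered block of trials; sessions 1-2 belong
to day 1 and sessions 3-4 to day 2, with electrode repositioning in between.
All schedules in the evaluation module address trials through this container
and rely on its chronological ordering: any model scored on a trial may only
have been trained on strictly earlier trials.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np

from .features import EmgRecording, FeatureMatrix, rms_features

__all__ = ["Trial", "TrialDataset"]


@dataclass
class Trial:
    """One trial: raw sEMG plus time-aligned force and stimulus traces.

    Before featurization ``emg`` has shape ``(T, C)`` and ``force`` /
    ``stimulus`` have shape ``(T, n_dofs)``.  After featurization
    ``features`` holds the ``(W, C)`` RMS matrix and ``force`` / ``stimulus``
    are the window-aligned ``(W, n_dofs)`` targets (the value at each
    window's final sample).  Indices are 1-based, following the protocol's
    own numbering ("first and tenth trial").
    """

    emg: np.ndarray
    force: np.ndarray
    stimulus: np.ndarray
    trial_index: int
    session_index: int
    day_index: int
    sample_rate: float = 100.0
    features: FeatureMatrix | None = None

    @property
    def is_featurized(self) -> bool:
        return self.features is not None

    @property
    def inputs(self) -> np.ndarray:
        """Regressor inputs: RMS features if featurized, raw sEMG otherwise."""
        return self.features.features if self.features is not None else self.emg

    @property
    def n_dofs(self) -> int:
        return self.force.shape[1]

    def featurized(self, window_length: int = 20, increment: int = 1) -> "Trial":
        """Return a copy with RMS features and window-aligned targets."""
        fm = rms_features(
            EmgRecording(self.emg, self.sample_rate),
            window_length=window_length,
            increment=increment,
        )
        idx = fm.target_alignment
        return replace(
            self,
            features=fm,
            force=self.force[idx],
            stimulus=self.stimulus[idx],
        )


@dataclass
class TrialDataset:
    """Ordered sessions of ordered trials, plus dataset-level metadata."""

    sessions: list[list[Trial]]
    seed: int | None = None
    config: dict | None = None

    # -- structure --------------------------------------------------------

    @property
    def n_sessions(self) -> int:
        return len(self.sessions)

    @property
    def n_trials(self) -> int:
        return sum(len(s) for s in self.sessions)

    @property
    def n_dofs(self) -> int:
        return self.sessions[0][0].n_dofs

    @property
    def n_channels(self) -> int:
        t = self.sessions[0][0]
        return t.inputs.shape[1]

    def trials(self) -> Iterator[Trial]:
        """All trials in chronological order."""
        for session in self.sessions:
            yield from session

    def trial_list(self) -> list[Trial]:
        return list(self.trials())

    def validate_chronology(self) -> None:
        """Assert session/trial indices are strictly increasing in order."""
        last = (0, 0)
        for t in self.trials():
            key = (t.session_index, t.trial_index)
            if key <= last:
                raise ValueError(
                    f"trials out of chronological order at session "
                    f"{t.session_index}, trial {t.trial_index}"
                )
            last = key

    # -- transforms -------------------------------------------------------

    def featurized(
        self, window_length: int = 20, increment: int = 1
    ) -> "TrialDataset":
        """RMS-featurize every trial (windows never cross trial boundaries)."""
        return TrialDataset(
            sessions=[
                [t.featurized(window_length, increment) for t in session]
                for session in self.sessions
            ],
            seed=self.seed,
            config=self.config,
        )

    # -- statistics -------------------------------------------------------

    def force_variance(self) -> np.ndarray:
        """Per-DOF variance of the measured force over *all* trials.

        This is the normalization constant of the nMSE metric: computed once
        per subject per DOF over the full recording, so batch and incremental
        settings share an identical error scale and the constant-mean
        predictor scores exactly 1.
        """
        force = np.concatenate([t.force for t in self.trials()], axis=0)
        return np.var(force, axis=0)
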