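"""Windowed RMS feature extraction for rectified multi-channel sEMG.

The electrodes emit an amplified, bandpass-filtered, rectified envelope, so
the only preprocessing needed before regression is a sliding-window root
mean square per channel: 200 ms windows (20 samples at 100 Hz) advanced one
sample at a time by default.  Windows never span trial boundaries, and each
window is aligned with the force/stimulus value at its *last* sample -- the
causal choice, the only one available in an online prosthesis controller.
A window length of 1 degenerates to using the raw samples directly, which is
the configuration used for low-latency teleoperation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EmgRecording",
    "FeatureMatrix",
    "rms_features",
    "subsample_windows",
    "RecordingTooShortError",
]


class RecordingTooShortError(ValueError):
    """Recording has fewer samples than one window."""


@dataclass(frozen=True)
class EmgRecording:
    """Rectified sEMG envelope samples, shape ``(T, C)``, all non-negative."""

    samples: np.ndarray
    sample_rate: float = 100.0

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 2:
            raise ValueError(f"samples must be a T x C matrix, got shape {s.shape}")
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if s.size and s.min() < 0:
            raise ValueError("rectified sEMG samples must be non-negative")
        object.__setattr__(self, "samples", s)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def channel_count(self) -> int:
        return self.samples.shape[1]


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-window, per-channel RMS values plus the window/target alignment.

    ``target_alignment[w]`` is the raw-sample index of window ``w``'s last
    sample; the regression target for the window is the force (or stimulus)
    at that index.
    """

    features: np.ndarray
    window_length: int
    increment: int
    target_alignment: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.features.shape[0]

    @property
    def channel_count(self) -> int:
        return self.features.shape[1]


def rms_features(
    rec: EmgRecording, window_length: int = 20, increment: int = 1
) -> FeatureMatrix:
    """Sliding-window RMS per channel.

    With increment 1 the number of windows is ``T - window_length + 1``;
    larger increments keep every ``increment``-th of those windows, starting
    from the first.  Raises :class:`RecordingTooShortError` when the
    recording is shorter than one window.
    """
    if window_length < 1:
        raise ValueError(f"window_length must be >= 1, got {window_length}")
    if increment < 1:
        raise ValueError(f"increment must be >= 1, got {increment}")
    T = rec.n_samples
    if T < window_length:
        raise RecordingTooShortError(
            f"recording has {T} samples, shorter than one window of "
            f"{window_length}"
        )
    sq = rec.samples ** 2
    # cumulative sum gives every window sum in O(T) per channel
    csum = np.vstack([np.zeros((1, rec.channel_count)), np.cumsum(sq, axis=0)])
    window_sums = csum[window_length:] - csum[:-window_length]
    feats = np.sqrt(np.maximum(window_sums, 0.0) / window_length)
    ends = np.arange(window_length - 1, T)
    if increment > 1:
        feats = feats[::increment]
        ends = ends[::increment]
    return FeatureMatrix(
        features=feats,
        window_length=window_length,
        increment=increment,
        target_alignment=ends,
    )


def subsample_windows(fm: FeatureMatrix, factor: int) -> FeatureMatrix:
    """Keep every ``factor``-th window (starting at the first), preserving
    the alignment indices of the kept windows.

    Used inside hyper-parameter search to cut the cost of cross-validation;
    equivalent to extracting with ``increment = fm.increment * factor``.
    """
    if factor < 1:
        raise ValueError(f"factor must be >= 1, got {factor}")
    if factor == 1:
        return fm
    return FeatureMatrix(
        features=fm.features[::factor],
        window_length=fm.window_length,
        increment=fm.increment * factor,
        target_alignment=fm.target_alignment[::factor],
    )
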