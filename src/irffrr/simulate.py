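"""Synthetic multi-session sEMG / finger-force / stimulus generator.

No public recordings exist for the multi-day finger-force protocol this
package evaluates, so this module emulates its essential structure:

* a visual stimulus per trial that activates the five fingers in turn
  (thumb first), each activation rising smoothly (square-sinusoidal ramp)
  to a plateau of 80% MVC held for 1.5, 3 or 4.5 s, separated by rests;
* measured forces that track the stimulus open-loop -- subjects see only the
  stimulus, not their own force -- with realized plateau amplitudes varying
  between roughly 40 and 100% MVC from one activation to the next, plus a
  smooth tracking error;
* a 10-channel rectified sEMG envelope at 100 Hz obtained by mixing a
  monotone *saturating* nonlinearity of the per-finger forces through a
  non-negative synergy/cross-talk matrix (so a linear force decoder is
  provably mis-specified), degraded by two nonstationarities:
  an exponential within-session gain drift ("electrode warm-up", strongest
  in the first session of each day) and a between-day multiplicative
  perturbation of the mixing matrix (electrode repositioning);
* the session layout of the protocol: 4 sessions x 18 trials, two sessions
  per day, day boundary after session 2.

Forces and stimuli are expressed as fractions of MVC (MVC = 1.0 per finger);
sEMG is in arbitrary non-negative units.  All randomness flows from a single
seed through ``numpy.random.SeedSequence`` spawning, so datasets are
bit-reproducible.  Drift and shift magnitudes have no measured ground truth;
the defaults are chosen to produce the qualitative degradation patterns seen
in real multi-day recordings (see docs/methods.md) and are fully
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .dataset import Trial, TrialDataset

__all__ = [
    "StimulusProfile",
    "SyntheticConfig",
    "GRASP_PATTERNS",
    "generate_stimulus_trial",
    "generate_force",
    "generate_emg",
    "generate_dataset",
    "generate_grasp_patterns",
    "base_mixing",
    "day_mixing",
    "saturating_nonlinearity",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusProfile:
    """Shape of one finger activation in the visual stimulus.

    The on/offset follows a square-sinusoidal (sin^2) ramp between rest and
    an 80% MVC plateau; the plateau duration is drawn per activation from
    three fixed values, and activations are separated by rests of a few
    seconds.
    """

    plateau_level: float = 0.8
    plateau_durations: tuple[float, ...] = (1.5, 3.0, 4.5)
    ramp_duration: float = 1.0
    rest_duration: float = 3.0
    sample_rate: float = 100.0

    def __post_init__(self) -> None:
        if not 0 < self.plateau_level <= 1:
            raise ValueError("plateau_level must lie in (0, 1] (fraction of MVC)")
        if min(self.plateau_durations) <= 0 or self.ramp_duration <= 0:
            raise ValueError("durations must be positive")


@dataclass(frozen=True)
class SyntheticConfig:
    """All generator parameters.

    Forces are fractions of MVC; time constants in seconds.  ``mixing`` may
    be supplied explicitly (channels x dofs, non-negative); by default a
    smooth synergy pattern with a cross-talk floor is built so that every
    finger drives at least two channels and every channel responds to at
    least one finger.
    """

    channels: int = 10
    dofs: int = 5
    sessions: int = 4
    trials_per_session: int = 18
    sessions_per_day: int = 2
    profile: StimulusProfile = field(default_factory=StimulusProfile)
    # EMG model
    nonlin_exponent: float = 0.6
    nonlin_k: float = 0.3
    crosstalk_floor: float = 0.08
    mixing: np.ndarray | None = None
    # noise (multiplicative log-normal when active, folded-normal baseline)
    noise_sd: float = 0.1
    rest_noise_sd: float = 0.01
    # force tracking
    force_inconsistency_range: tuple[float, float] = (0.4, 1.0)
    tracking_error_sd: float = 0.03
    force_noise_sd: float = 0.005
    # nonstationarity
    within_session_drift: float = 0.3
    drift_tau_s: float = 300.0
    warmup_sessions: tuple[int, ...] = (1, 3)
    between_day_shift: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.force_inconsistency_range
        if not (0 < lo <= hi <= 1.5):
            raise ValueError(
                "force_inconsistency_range must satisfy 0 < low <= high"
            )
        if self.channels < 1 or self.dofs < 1:
            raise ValueError("channels and dofs must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.mixing is not None:
            d["mixing"] = np.asarray(self.mixing).tolist()
        return d


#: canonical multi-finger grasp patterns (thumb, index, middle, ring, little),
#: as fractions of each finger's full flexion
GRASP_PATTERNS: dict[str, tuple[float, ...]] = {
    "rest": (0.0, 0.0, 0.0, 0.0, 0.0),
    "pinch": (1.0, 1.0, 0.0, 0.0, 0.0),   # thumb + index, others at rest
    "power": (1.0, 1.0, 1.0, 1.0, 1.0),   # all fingers flexed
    "point": (1.0, 0.0, 1.0, 1.0, 1.0),   # all flexed except index
}


# ---------------------------------------------------------------------------
# Stimulus
# ---------------------------------------------------------------------------


def _activation_envelope(
    profile: StimulusProfile, plateau_duration: float
) -> np.ndarray:
    """One activation: sin^2 ramp up, constant plateau, sin^2 ramp down.

    Normalized to peak 1; multiply by the plateau level (and pattern) to get
    stimulus units.
    """
    rate = profile.sample_rate
    n_ramp = int(round(profile.ramp_duration * rate))
    n_plateau = int(round(plateau_duration * rate))
    # ramps exclude the plateau value itself, so exactly n_plateau samples
    # sit at the plateau level
    t = np.arange(1, n_ramp + 1) / (n_ramp + 1)
    up = np.sin(0.5 * np.pi * t) ** 2
    down = up[::-1]
    return np.concatenate([up, np.ones(n_plateau), down])


def generate_stimulus_trial(
    profile: StimulusProfile,
    dof_order: tuple[int, ...] | list[int],
    rng: np.random.Generator,
    n_dofs: int = 5,
) -> np.ndarray:
    """Stimulus for one trial: each finger activated once, in ``dof_order``
    (thumb first in the standard protocol), separated by rests.

    At every sample at most one DOF is non-zero, which is what makes a
    single force sensor sufficient: non-activated fingers are assumed to
    exert zero force.
    """
    rate = profile.sample_rate
    n_rest = int(round(profile.rest_duration * rate))
    segments: list[np.ndarray] = [np.zeros((n_rest, n_dofs))]
    for dof in dof_order:
        dur = float(rng.choice(profile.plateau_durations))
        env = _activation_envelope(profile, dur) * profile.plateau_level
        block = np.zeros((env.size + n_rest, n_dofs))
        block[: env.size, dof] = env
        segments.append(block)
    return np.concatenate(segments, axis=0)


# ---------------------------------------------------------------------------
# Force
# ---------------------------------------------------------------------------


def _active_segments(x: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs where ``x > 0``."""
    mask = np.concatenate([[False], x > 0, [False]])
    edges = np.flatnonzero(np.diff(mask.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def generate_force(
    stimulus: np.ndarray, cfg: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    """Measured force produced while tracking ``stimulus`` open-loop.

    Each activation's realized plateau amplitude is drawn from a normal
    distribution centred on the middle of ``force_inconsistency_range`` with
    standard deviation one fifth of the band, clipped to the band (in MVC
    units): subjects over- and under-shoot since their own force is not
    displayed, typically by a moderate amount, occasionally reaching the
    band's extremes.  A smooth tracking error modulated by the activation
    envelope is added, plus small zero-mean sensor noise.  Force is zero at
    rest up to noise.
    """
    level = cfg.profile.plateau_level
    force = np.zeros_like(stimulus)
    lo, hi = cfg.force_inconsistency_range
    for d in range(stimulus.shape[1]):
        col = stimulus[:, d]
        for start, stop in _active_segments(col):
            seg = col[start:stop]
            amp = float(
                np.clip(rng.normal(0.5 * (lo + hi), 0.2 * (hi - lo)), lo, hi)
            )
            realized = seg * (amp / level)
            if cfg.tracking_error_sd > 0:
                wobble = gaussian_filter1d(
                    rng.normal(0.0, 1.0, seg.size), sigma=25.0, mode="constant"
                )
                sd = wobble.std()
                if sd > 0:
                    realized = realized + (
                        cfg.tracking_error_sd * wobble / sd * (seg / level)
                    )
            force[start:stop, d] = realized
    if cfg.force_noise_sd > 0:
        force = force + rng.normal(0.0, cfg.force_noise_sd, force.shape)
    return np.clip(force, 0.0, None)


# ---------------------------------------------------------------------------
# EMG
# ---------------------------------------------------------------------------


def saturating_nonlinearity(
    f: np.ndarray, exponent: float = 0.6, k: float = 0.3
) -> np.ndarray:
    """Monotone saturating force -> muscle-activation map.

    ``h(f) = (1 + k) * f^e / (f^e + k)`` with ``h(0) = 0`` and ``h(1) = 1``:
    concave and compressive, emulating the practical breakdown of the
    linear RMS-force relationship (cross-talk, amplifier saturation), so
    that a linear decoder is structurally mis-specified.
    """
    fe = np.clip(f, 0.0, None) ** exponent
    return (1.0 + k) * fe / (fe + k)


def base_mixing(cfg: SyntheticConfig) -> np.ndarray:
    """Deterministic channels x dofs synergy matrix with cross-talk.

    Each finger projects a smooth Gaussian bump onto the electrode array
    plus a uniform cross-talk floor, so every DOF drives >= 2 channels and
    every channel responds to >= 1 DOF.  Columns are normalized to peak 1.
    """
    if cfg.mixing is not None:
        M = np.asarray(cfg.mixing, dtype=float)
        if M.shape != (cfg.channels, cfg.dofs):
            raise ValueError(
                f"mixing must have shape {(cfg.channels, cfg.dofs)}, got {M.shape}"
            )
        if M.min() < 0:
            raise ValueError("mixing entries must be non-negative")
        return M
    positions = np.arange(cfg.channels, dtype=float)
    centers = (np.arange(cfg.dofs) + 0.5) * cfg.channels / cfg.dofs
    width = 1.2 * cfg.channels / 10.0
    M = np.exp(-((positions[:, None] - centers[None, :]) ** 2) / (2 * width**2))
    M += cfg.crosstalk_floor
    return M / M.max(axis=0, keepdims=True)


def day_mixing(cfg: SyntheticConfig, day_index: int) -> np.ndarray:
    """Mixing matrix in effect on ``day_index`` (1-based).

    Day 1 uses the base matrix; later days apply a multiplicative log-normal
    perturbation of magnitude ``between_day_shift`` per entry, drawn once
    per day from the dataset seed -- the electrode band is repositioned only
    between days, never between same-day sessions.
    """
    M = base_mixing(cfg)
    if day_index <= 1 or cfg.between_day_shift == 0:
        return M
    ss = np.random.SeedSequence([cfg.seed, 7919, day_index])
    rng = np.random.default_rng(ss)
    return M * np.exp(cfg.between_day_shift * rng.normal(size=M.shape))


def _session_drift_amplitudes(
    cfg: SyntheticConfig, session_index: int
) -> np.ndarray:
    """Per-channel warm-up gain offsets for a session (1-based index)."""
    if (
        cfg.within_session_drift == 0
        or session_index not in cfg.warmup_sessions
    ):
        return np.zeros(cfg.channels)
    ss = np.random.SeedSequence([cfg.seed, 104729, session_index])
    rng = np.random.default_rng(ss)
    return rng.uniform(
        -cfg.within_session_drift, cfg.within_session_drift, cfg.channels
    )


def generate_emg(
    force: np.ndarray,
    cfg: SyntheticConfig,
    session_index: int,
    day_index: int,
    time_in_session: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Rectified sEMG envelope for one trial's force trace.

    ``emg = g(t) * [mixing_day @ h(force)] + noise`` where ``h`` is the
    saturating nonlinearity, ``mixing_day`` carries the between-day
    electrode-repositioning shift, and ``g`` is the within-session warm-up
    gain ``1 + a_c * exp(-t / tau)`` (channel-specific, decaying over
    ~``drift_tau_s``, active in the first session of each day by default).
    Noise is multiplicative log-normal where the signal is active plus a
    small folded-normal floor, so the output is non-negative by
    construction.  ``time_in_session`` is the trial's start time (s).
    """
    M = day_mixing(cfg, day_index)
    clean = saturating_nonlinearity(
        force, cfg.nonlin_exponent, cfg.nonlin_k
    ) @ M.T
    T = force.shape[0]
    amps = _session_drift_amplitudes(cfg, session_index)
    if np.any(amps != 0):
        t = time_in_session + np.arange(T) / cfg.profile.sample_rate
        gain = 1.0 + amps[None, :] * np.exp(-t / cfg.drift_tau_s)[:, None]
        clean = clean * gain
    emg = clean
    if cfg.noise_sd > 0:
        emg = emg * np.exp(rng.normal(0.0, cfg.noise_sd, emg.shape))
    if cfg.rest_noise_sd > 0:
        emg = emg + np.abs(rng.normal(0.0, cfg.rest_noise_sd, emg.shape))
    return np.clip(emg, 0.0, None)


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------


def generate_dataset(cfg: SyntheticConfig) -> TrialDataset:
    """Full multi-session dataset following the recording protocol.

    Default layout: 4 sessions x 18 trials of 5 sequential finger
    activations each (90 activations per session), two sessions per day.
    Deterministic given ``cfg.seed``.
    """
    ss = np.random.SeedSequence([cfg.seed, 15485863])
    streams = iter(ss.spawn(cfg.sessions * cfg.trials_per_session))
    sessions: list[list[Trial]] = []
    for s in range(1, cfg.sessions + 1):
        day = (s - 1) // cfg.sessions_per_day + 1
        time_in_session = 0.0
        trials: list[Trial] = []
        for t in range(1, cfg.trials_per_session + 1):
            rng = np.random.default_rng(next(streams))
            stim = generate_stimulus_trial(
                cfg.profile, tuple(range(cfg.dofs)), rng, n_dofs=cfg.dofs
            )
            force = generate_force(stim, cfg, rng)
            emg = generate_emg(force, cfg, s, day, time_in_session, rng)
            trials.append(
                Trial(
                    emg=emg,
                    force=force,
                    stimulus=stim,
                    trial_index=t,
                    session_index=s,
                    day_index=day,
                    sample_rate=cfg.profile.sample_rate,
                )
            )
            time_in_session += stim.shape[0] / cfg.profile.sample_rate
        sessions.append(trials)
    return TrialDataset(sessions=sessions, seed=cfg.seed, config=cfg.to_dict())


def generate_grasp_patterns(
    cfg: SyntheticConfig,
    patterns: list[str] = ("rest", "pinch", "power", "point"),
    repetitions: int = 2,
    rng: np.random.Generator | None = None,
) -> TrialDataset:
    """Single-session dataset of simultaneous multi-finger grasp patterns.

    Each trial holds one activation of a named pattern (pinch, power grasp,
    pointing, rest), scaled per finger by the pattern's activation levels;
    all active fingers move together, exercising joint multi-output
    prediction.  Two repetitions per pattern by default.
    """
    for name in patterns:
        if name not in GRASP_PATTERNS:
            raise ValueError(
                f"unknown grasp pattern {name!r}; known: {sorted(GRASP_PATTERNS)}"
            )
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 32452843]))
    trials: list[Trial] = []
    rate = cfg.profile.sample_rate
    n_rest = int(round(cfg.profile.rest_duration * rate))
    index = 1
    time_in_session = 0.0
    for _rep in range(repetitions):
        for name in patterns:
            levels = np.asarray(GRASP_PATTERNS[name][: cfg.dofs])
            dur = float(rng.choice(cfg.profile.plateau_durations))
            env = _activation_envelope(cfg.profile, dur)
            stim = np.zeros((n_rest + env.size + n_rest, cfg.dofs))
            stim[n_rest : n_rest + env.size] = (
                env[:, None] * levels[None, :] * cfg.profile.plateau_level
            )
            force = generate_force(stim, cfg, rng)
            emg = generate_emg(force, cfg, 1, 1, time_in_session, rng)
            trials.append(
                Trial(
                    emg=emg,
                    force=force,
                    stimulus=stim,
                    trial_index=index,
                    session_index=1,
                    day_index=1,
                    sample_rate=rate,
                )
            )
            index += 1
            time_in_session += stim.shape[0] / rate
    return TrialDataset(sessions=[trials], seed=cfg.seed, config=cfg.to_dict())
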