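"""Metrics, hyper-parameter search and the train/test schedules.

Three experimental settings are implemented, all operating on a featurized
:class:`~irffrr.dataset.TrialDataset` in strict chronological order (a model
scored on a trial has never seen a later trial):

* **batch** -- train once on the first three trials of session 1 (optionally:
  of *each* session) and score every remaining trial; shows how a frozen
  model degrades as the signal drifts.
* **incremental** -- same initial training, then constant-time incremental
  updates on the first and tenth trial of every session, scoring all others
  (10 training trials in total on the standard 4 x 18 layout).
* **realistic** -- identical schedule to incremental, but the training
  targets are the *stimulus* shown to the subject (variant 1) or a binary
  version thresholded at 50% MVC (variant 2), emulating amputees who cannot
  produce measurable ground-truth forces.  Scoring is always against the
  measured force.

Per scored trial and per DOF two measures are recorded: the normalized mean
squared error nMSE = MSE / Var(y), with the variance computed once per
subject per DOF over *all* trials (so nMSE = 1 is exactly the constant-mean
predictor and R^2 = 1 - nMSE), and the Pearson correlation, which ignores
constant prediction offsets and so tracks whether the right finger moves
even when the force magnitude is off.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .dataset import Trial, TrialDataset
from .features import subsample_windows
from .learners import IncrementalUnsupportedError, make_learner

__all__ = [
    "DegenerateTargetError",
    "UndefinedCorrelationError",
    "nmse",
    "pearson_corr",
    "r_squared_from_nmse",
    "HyperGrid",
    "LearnerSpec",
    "grid_search_cv",
    "EvaluationReport",
    "run_batch_setting",
    "run_incremental_setting",
    "run_realistic_setting",
    "incremental_schedule",
    "batch_schedule",
]

MVC = 1.0  # forces and stimuli are stored as fractions of MVC


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


class DegenerateTargetError(ValueError):
    """Target variance is zero: nMSE is undefined."""


class UndefinedCorrelationError(ValueError):
    """Pearson correlation undefined (constant input)."""


def nmse(y_true: np.ndarray, y_pred: np.ndarray, norm_variance: float) -> float:
    """MSE divided by an externally supplied variance.

    The normalization variance is computed once per subject per DOF over all
    trials -- not per test trial -- so batch and incremental settings share
    one error scale, and predicting the global mean scores exactly 1.
    """
    if norm_variance <= 0:
        raise DegenerateTargetError(
            f"normalization variance must be positive, got {norm_variance}"
        )
    y_true = np.asarray(y_true, dtype=float).reshape(-1)
    y_pred = np.asarray(y_pred, dtype=float).reshape(-1)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("y_true and y_pred must be equal-length, non-empty")
    return float(np.mean((y_true - y_pred) ** 2) / norm_variance)


def pearson_corr(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Pearson correlation coefficient; raises on constant input."""
    y_true = np.asarray(y_true, dtype=float).reshape(-1)
    y_pred = np.asarray(y_pred, dtype=float).reshape(-1)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    st, sp = y_true.std(), y_pred.std()
    if st == 0 or sp == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    r = float(
        np.mean((y_true - y_true.mean()) * (y_pred - y_pred.mean())) / (st * sp)
    )
    return min(1.0, max(-1.0, r))


def r_squared_from_nmse(value: float) -> float:
    """Coefficient of determination: ``R^2 = 1 - nMSE``."""
    return 1.0 - value


# ---------------------------------------------------------------------------
# Hyper-parameter search
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HyperGrid:
    """Power-of-two grid over the regularizer and kernel bandwidth.

    Default: ``lambda in {2^-12 .. 2^5}`` (18 values) crossed with
    ``gamma in {2^-8 .. 2^7}`` (16 values), 288 combinations.
    """

    lambda_exponents: tuple[int, int] = (-12, 5)
    gamma_exponents: tuple[int, int] = (-8, 7)
    base: float = 2.0

    def lambdas(self) -> list[float]:
        lo, hi = self.lambda_exponents
        return [self.base**e for e in range(lo, hi + 1)]

    def gammas(self) -> list[float]:
        lo, hi = self.gamma_exponents
        return [self.base**e for e in range(lo, hi + 1)]

    def pairs(self) -> list[tuple[float, float]]:
        """All (lambda, gamma) pairs, ordered so that ties on CV error are
        broken toward larger lambda, then smaller gamma."""
        out = [
            (lam, gam)
            for lam in sorted(self.lambdas(), reverse=True)
            for gam in sorted(self.gammas())
        ]
        if not out:
            raise ValueError("empty hyper-parameter grid")
        return out


@dataclass(frozen=True)
class LearnerSpec:
    """Recipe for building a learner adapter inside the harness.

    ``kind`` is one of ``rr`` (linear ridge), ``krr`` (exact kernel ridge)
    or ``irffrr`` (incremental ridge on ``rff_dim`` random Fourier
    features).  ``bandwidth`` is ignored by ``rr``.
    """

    kind: str = "irffrr"
    rff_dim: int = 1000
    regularizer: float = 1.0
    bandwidth: float = 2.47

    def make(self, n_inputs: int, n_outputs: int, seed: int = 0):
        kwargs: dict = {"regularizer": self.regularizer}
        if self.kind in ("irffrr", "krr"):
            kwargs["bandwidth"] = self.bandwidth
        if self.kind == "irffrr":
            kwargs["n_features"] = self.rff_dim
            kwargs["seed"] = seed
        return make_learner(self.kind, n_inputs, n_outputs, **kwargs)

    @property
    def supports_update(self) -> bool:
        return self.kind != "krr"

    def label(self) -> str:
        return f"irffrr{self.rff_dim}" if self.kind == "irffrr" else self.kind


def _stack(trials: list[Trial], targets: list[np.ndarray] | None = None):
    X = np.concatenate([t.inputs for t in trials], axis=0)
    if targets is None:
        Y = np.concatenate([t.force for t in trials], axis=0)
    else:
        Y = np.concatenate(targets, axis=0)
    return X, Y


def grid_search_cv(
    train_trials: list[Trial],
    grid: HyperGrid,
    learner_spec: LearnerSpec,
    subsample_factor: int = 4,
    runs: int = 1,
    seed: int = 0,
) -> tuple[float, float]:
    """Leave-one-trial-out cross-validation over the hyper-parameter grid.

    Each fold is exactly one training trial, so distributional differences
    between trials are reflected in the validation error.  Windows are
    regularly subsampled by ``subsample_factor`` during the search only.
    For randomized learners the fold errors are averaged over ``runs``
    feature-map seeds.  Returns the (lambda, gamma) pair minimizing the mean
    validation nMSE over folds, DOFs and runs; ties break toward larger
    lambda, then smaller gamma.
    """
    if len(train_trials) < 2:
        raise ValueError("grid search requires at least two training trials")
    folds = []
    for t in train_trials:
        if t.features is None:
            raise ValueError("grid search expects featurized trials")
        fm = subsample_windows(t.features, subsample_factor)
        sel = slice(None, None, subsample_factor)
        folds.append((fm.features, t.force[sel]))
    all_targets = np.concatenate([y for _, y in folds], axis=0)
    norm_var = np.var(all_targets, axis=0)
    if np.any(norm_var <= 0):
        raise DegenerateTargetError("a DOF is constant over the training trials")
    n_inputs = folds[0][0].shape[1]
    p = all_targets.shape[1]
    n_runs = runs if learner_spec.kind == "irffrr" else 1

    best_pair, best_err = None, math.inf
    for lam, gam in grid.pairs():
        spec = dc_replace(learner_spec, regularizer=lam, bandwidth=gam)
        errs = []
        for k in range(len(folds)):
            Xv, Yv = folds[k]
            Xt = np.concatenate(
                [x for i, (x, _) in enumerate(folds) if i != k], axis=0
            )
            Yt = np.concatenate(
                [y for i, (_, y) in enumerate(folds) if i != k], axis=0
            )
            intercept = Yt.mean(axis=0)
            for run in range(n_runs):
                learner = spec.make(n_inputs, p, seed=seed * 1009 + run)
                learner.fit(Xt, Yt - intercept)
                pred = learner.predict(Xv) + intercept
                errs.extend(
                    nmse(Yv[:, d], pred[:, d], norm_var[d]) for d in range(p)
                )
        err = float(np.mean(errs))
        if err < best_err:
            best_err, best_pair = err, (lam, gam)
    return best_pair


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Per-run, per-trial, per-DOF scores for one experimental setting.

    ``nmse_scores`` and ``corr_scores`` have shape ``(runs, n_trials,
    n_dofs)`` with NaN marking training trials (never scored) and, for the
    correlation, scored trials whose prediction was constant.
    """

    setting: str
    learner: str
    nmse_scores: np.ndarray
    corr_scores: np.ndarray
    trained_mask: np.ndarray
    session_index: np.ndarray
    trial_index: np.ndarray
    runs: int
    hyperparameters: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return self.trained_mask.size

    @property
    def n_training_trials(self) -> int:
        return int(self.trained_mask.sum())

    @property
    def n_scored_trials(self) -> int:
        return int((~self.trained_mask).sum())

    def per_trial_curve(self, metric: str = "nmse") -> np.ndarray:
        """Learning curve: mean over runs and DOFs; NaN at training trials."""
        scores = self.nmse_scores if metric == "nmse" else self.corr_scores
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(scores, axis=(0, 2))  # training trials -> NaN

    def overall(self, metric: str = "nmse", sessions=None) -> float:
        """Mean over all scored trials, runs and DOFs (optionally restricted
        to a set of 1-based session indices)."""
        scores = self.nmse_scores if metric == "nmse" else self.corr_scores
        keep = ~self.trained_mask
        if sessions is not None:
            keep = keep & np.isin(self.session_index, list(sessions))
        return float(np.nanmean(scores[:, keep, :]))

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: run, session, trial, dof, nmse, corr."""
        runs, n_trials, p = self.nmse_scores.shape
        r, t, d = np.meshgrid(
            np.arange(runs), np.arange(n_trials), np.arange(p), indexing="ij"
        )
        return pd.DataFrame(
            {
                "setting": self.setting,
                "learner": self.learner,
                "run": r.ravel(),
                "session": self.session_index[t.ravel()],
                "trial": self.trial_index[t.ravel()],
                "dof": d.ravel(),
                "trained": self.trained_mask[t.ravel()],
                "nmse": self.nmse_scores.ravel(),
                "corr": self.corr_scores.ravel(),
            }
        )

    def summary(self) -> str:
        lines = [
            f"setting: {self.setting}   learner: {self.learner}   "
            f"runs: {self.runs}",
            f"trials: {self.n_trials} ({self.n_training_trials} training, "
            f"{self.n_scored_trials} scored)",
            f"overall nMSE: {self.overall('nmse'):.3f}   "
            f"overall corr: {self.overall('corr'):.3f}",
        ]
        for s in np.unique(self.session_index):
            lines.append(
                f"  session {s}: nMSE {self.overall('nmse', sessions=[s]):.3f}"
                f"   corr {self.overall('corr', sessions=[s]):.3f}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Schedules
# ---------------------------------------------------------------------------

#: roles a trial can play in a schedule
_BATCH, _UPDATE, _TEST = "batch", "update", "test"


def batch_schedule(
    ds: TrialDataset, retrain_each_session: bool
) -> list[tuple[str, int]]:
    """Role of every trial (chronological): ``(role, model_group)``.

    Group ``g`` identifies which batch model scores the trial; with
    ``retrain_each_session`` a fresh model is trained from scratch on the
    first three trials of every session.
    """
    roles = []
    for t in ds.trials():
        if len(ds.sessions[t.session_index - 1]) < 4:
            raise ValueError(
                f"session {t.session_index} has fewer than 4 trials; "
                "cannot split into training and test"
            )
        group = t.session_index - 1 if retrain_each_session else 0
        if t.trial_index <= 3 and (retrain_each_session or t.session_index == 1):
            roles.append((_BATCH, group))
        else:
            roles.append((_TEST, group))
    return roles


def incremental_schedule(ds: TrialDataset) -> list[tuple[str, int]]:
    """Initial batch on the first three trials of session 1, then an
    incremental update on the first and tenth trial of every session (trial
    1 of session 1 is already part of the initial batch): 3 + 1 + 3*2 = 10
    training trials on the standard four-session layout."""
    roles = []
    for t in ds.trials():
        if t.session_index == 1 and t.trial_index <= 3:
            roles.append((_BATCH, 0))
        elif t.trial_index in (1, 10):
            roles.append((_UPDATE, 0))
        else:
            roles.append((_TEST, 0))
    return roles


# ---------------------------------------------------------------------------
# Harness
# ---------------------------------------------------------------------------


def _training_targets(trial: Trial, target_mode: str) -> np.ndarray:
    if target_mode == "force":
        return trial.force
    if target_mode == "stimulus":
        return trial.stimulus
    if target_mode == "binary":
        plateau = float(np.max(trial.stimulus)) if trial.stimulus.size else 0.0
        return np.where(trial.stimulus >= 0.5 * MVC, plateau, 0.0)
    raise ValueError(f"unknown target mode {target_mode!r}")


def _run_schedule(
    ds: TrialDataset,
    learner_spec: LearnerSpec,
    roles: list[tuple[str, int]],
    setting: str,
    runs: int,
    seed: int,
    target_mode: str,
) -> EvaluationReport:
    trials = ds.trial_list()
    ds.validate_chronology()
    if any(r == _UPDATE for r, _ in roles) and not learner_spec.supports_update:
        raise IncrementalUnsupportedError(
            f"learner {learner_spec.kind!r} does not support incremental "
            "updates; it can only be used in the batch settings"
        )
    norm_var = ds.force_variance()
    if np.any(norm_var <= 0):
        raise DegenerateTargetError(
            "a DOF has zero force variance over the dataset"
        )
    p = ds.n_dofs
    n_inputs = trials[0].inputs.shape[1]
    n_trials = len(trials)
    trained_mask = np.array([r != _TEST for r, _ in roles])
    n_runs = runs if learner_spec.kind == "irffrr" else 1
    nmse_scores = np.full((n_runs, n_trials, p), np.nan)
    corr_scores = np.full((n_runs, n_trials, p), np.nan)

    # batch groups: positions of the trials each batch model trains on
    groups: dict[int, list[int]] = {}
    for pos, (role, group) in enumerate(roles):
        if role == _BATCH:
            groups.setdefault(group, []).append(pos)

    rng = np.random.SeedSequence([seed, 2862933555])
    run_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in rng.spawn(n_runs)]

    for run, run_seed in enumerate(run_seeds):
        learner = None
        intercept = None
        current_group = None
        last_train_pos = -1
        for pos, (role, group) in enumerate(roles):
            trial = trials[pos]
            if role in (_BATCH, _UPDATE) and group != current_group:
                # train this group's batch model on its (contiguous) trials
                members = groups[group]
                batch_trials = [trials[i] for i in members]
                targets = [
                    _training_targets(t, target_mode) for t in batch_trials
                ]
                X, Y = _stack(batch_trials, targets)
                intercept = Y.mean(axis=0)
                learner = learner_spec.make(n_inputs, p, seed=run_seed)
                learner.fit(X, Y - intercept)
                last_train_pos = max(members)
                current_group = group
                continue
            if role == _BATCH:
                continue
            if role == _UPDATE:
                Y = _training_targets(trial, target_mode)
                learner.update(trial.inputs, Y - intercept)
                last_train_pos = pos
                continue
            # scoring: temporal causality is a hard invariant
            if pos <= last_train_pos and current_group == group:
                raise AssertionError(
                    "temporal causality violated: scoring a trial that "
                    "precedes training data"
                )
            pred = learner.predict(trial.inputs) + intercept
            for d in range(p):
                nmse_scores[run, pos, d] = nmse(
                    trial.force[:, d], pred[:, d], norm_var[d]
                )
                try:
                    corr_scores[run, pos, d] = pearson_corr(
                        trial.force[:, d], pred[:, d]
                    )
                except UndefinedCorrelationError:
                    pass  # recorded as NaN, excluded from averages

    if n_runs < runs:  # deterministic learner: replicate the single run
        nmse_scores = np.repeat(nmse_scores, runs, axis=0)
        corr_scores = np.repeat(corr_scores, runs, axis=0)

    return EvaluationReport(
        setting=setting,
        learner=learner_spec.label(),
        nmse_scores=nmse_scores,
        corr_scores=corr_scores,
        trained_mask=trained_mask,
        session_index=np.array([t.session_index for t in trials]),
        trial_index=np.array([t.trial_index for t in trials]),
        runs=runs,
        hyperparameters={
            "lambda": learner_spec.regularizer,
            "gamma": learner_spec.bandwidth,
            "rff_dim": learner_spec.rff_dim
            if learner_spec.kind == "irffrr"
            else None,
        },
    )


def run_batch_setting(
    ds: TrialDataset,
    learner_spec: LearnerSpec,
    retrain_each_session: bool = False,
    runs: int = 1,
    seed: int = 0,
) -> EvaluationReport:
    """Batch setting: train on the first three trials (of session 1, or of
    each session when ``retrain_each_session``), score everything else in
    chronological order.  The training-output mean is subtracted as an
    intercept and re-added before scoring."""
    roles = batch_schedule(ds, retrain_each_session)
    name = "batch-per-session" if retrain_each_session else "batch"
    return _run_schedule(ds, learner_spec, roles, name, runs, seed, "force")


def run_incremental_setting(
    ds: TrialDataset,
    learner_spec: LearnerSpec,
    runs: int = 1,
    seed: int = 0,
) -> EvaluationReport:
    """Incremental setting: initial batch on session 1 trials 1-3, then
    constant-time updates on the first and tenth trial of every session;
    all other trials are scored.  The intercept and hyper-parameters are
    fixed at initial training and never re-estimated mid-stream."""
    roles = incremental_schedule(ds)
    return _run_schedule(
        ds, learner_spec, roles, "incremental", runs, seed, "force"
    )


def run_realistic_setting(
    ds: TrialDataset,
    variant: str,
    learner_spec: LearnerSpec,
    runs: int = 1,
    seed: int = 0,
) -> EvaluationReport:
    """Realistic settings: the incremental schedule with stimulus-derived
    training targets (``graded_stimulus``: the stimulus itself;
    ``binary_stimulus``: stimulus thresholded at 50% MVC to {0, plateau}),
    scored against measured force."""
    modes = {"graded_stimulus": "stimulus", "binary_stimulus": "binary"}
    if variant not in modes:
        raise ValueError(
            f"unknown variant {variant!r}; choose from {sorted(modes)}"
        )
    roles = incremental_schedule(ds)
    name = "realistic1" if variant == "graded_stimulus" else "realistic2"
    return _run_schedule(
        ds, learner_spec, roles, name, runs, seed, modes[variant]
    )
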