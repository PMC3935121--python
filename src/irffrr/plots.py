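"""Per-trial learning-curve figures for the evaluation settings."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluation import EvaluationReport

__all__ = ["plot_learning_curves", "plot_convergence"]


def plot_learning_curves(
    reports: list[EvaluationReport], path: str | Path, title: str | None = None
) -> None:
    """nMSE and correlation per trial for one or more settings/learners.

    Session boundaries are drawn as vertical lines; training trials appear
    as gaps in the curves (they are never scored).
    """
    fig, axes = plt.subplots(2, 1, figsize=(9, 6), sharex=True)
    for report in reports:
        x = np.arange(1, report.n_trials + 1)
        label = f"{report.learner} ({report.setting})"
        axes[0].plot(x, report.per_trial_curve("nmse"), marker=".", label=label)
        axes[1].plot(x, report.per_trial_curve("corr"), marker=".", label=label)
    bounds = np.flatnonzero(np.diff(reports[0].session_index)) + 1.5
    for ax in axes:
        for b in bounds:
            ax.axvline(b, color="gray", lw=0.8, ls="--")
    axes[0].axhline(1.0, color="k", lw=0.8, ls=":", label="trivial baseline")
    axes[0].set_ylabel("nMSE")
    axes[1].set_ylabel("correlation")
    axes[1].set_xlabel("trial")
    axes[0].legend(fontsize=8)
    if title:
        axes[0].set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_convergence(
    dims: list[int],
    gaps: np.ndarray,
    path: str | Path,
) -> None:
    """Median (and IQR) |nMSE(iRFFRR_D) - nMSE(KRR)| as D grows."""
    gaps = np.asarray(gaps)
    med = np.median(gaps, axis=1)
    lo = np.percentile(gaps, 25, axis=1)
    hi = np.percentile(gaps, 75, axis=1)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.errorbar(dims, med, yerr=[med - lo, hi - med], marker="o", capsize=3)
    ax.set_xscale("log")
    ax.set_xlabel("number of random Fourier features D")
    ax.set_ylabel("|nMSE - nMSE(KRR)|")
    ax.set_title("Convergence of the random-feature approximation")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
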