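"""Outcome reactivation during choice and per-subject prioritization maps.

The classifier bank is applied to task epochs aligned to probability-stimulus
onset, giving a reactivation probability RP for each outcome, classifier
train time tau and task time tau'.  Per subject and (tau, tau') cell, the
trialwise difference RP_O1 - RP_O2 is regressed on the trialwise probability
difference P_O1 - P_O2 and absolute-reward difference |R_O1| - |R_O2|; the
two slopes are the subject's neural probability / reward prioritization.
Task timepoints after the response are censored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decode import ClassifierBank, EpochSet
from .task import TrialSpec

__all__ = [
    "ReactivationTensor",
    "PrioritizationMaps",
    "apply_bank_to_task",
    "first_level_maps",
    "MIN_TRIALS_PER_CELL",
]

MIN_TRIALS_PER_CELL = 3
MIN_TRAIN_MS = 20  # classifiers trained earlier than this are not applied


@dataclass
class ReactivationTensor:
    """RP[trial, outcome, train bin, task bin] with response censoring."""

    rp: np.ndarray  # (n_trials, 3, n_train_bins, n_task_bins)
    mask: np.ndarray  # (n_trials, n_task_bins); True = pre-response, usable
    train_times_ms: np.ndarray
    task_times_ms: np.ndarray

    def __post_init__(self) -> None:
        if np.any((self.rp < 0) | (self.rp > 1)):
            raise ValueError("reactivation probabilities must lie in [0, 1]")


@dataclass
class PrioritizationMaps:
    beta_prob: np.ndarray  # (n_train_bins, n_task_bins); NaN where undefined
    beta_rew: np.ndarray
    rp_os_mean: np.ndarray
    train_times_ms: np.ndarray
    task_times_ms: np.ndarray


def apply_bank_to_task(
    bank: ClassifierBank,
    task_epochs: EpochSet,
    responses_s: np.ndarray,
    min_train_ms: float = MIN_TRAIN_MS,
) -> ReactivationTensor:
    """Reactivation probabilities for every trial of choice-period data.

    ``responses_s`` holds per-trial response times in seconds; task bins at
    or after the response are masked out.  Test data is divided by the
    bank's stored training scale inside ``activation_probs``.
    """
    if task_epochs.alignment != "probability_stimulus":
        raise ValueError("task epochs must be aligned to probability-stimulus onset")
    responses_s = np.asarray(responses_s, float)
    if len(responses_s) != task_epochs.n_events:
        raise ValueError("one response time per task epoch required")
    keep = bank.train_times_ms >= min_train_ms
    probs = bank.activation_probs(task_epochs.data)[:, keep]  # (3, nt, nb, ne)
    rp = np.transpose(probs, (3, 0, 1, 2))
    mask = task_epochs.times_ms[None, :] < responses_s[:, None] * 1000.0
    return ReactivationTensor(
        rp=rp,
        mask=mask,
        train_times_ms=bank.train_times_ms[keep].copy(),
        task_times_ms=task_epochs.times_ms.copy(),
    )


def trial_regressors(trials: list[TrialSpec]) -> np.ndarray:
    """Per-trial [dP, d|R|] = [P_O1 - P_O2, |R_O1| - |R_O2|] (non-catch)."""
    out = np.empty((len(trials), 2))
    for i, t in enumerate(trials):
        if t.is_catch:
            raise ValueError("catch trials carry no probability stimulus")
        out[i, 0] = t.p_O1 - t.p_O2
        out[i, 1] = abs(t.r_O1) - abs(t.r_O2)
    return out


def first_level_maps(
    tensor: ReactivationTensor, trials: list[TrialSpec]
) -> PrioritizationMaps:
    """OLS of RP_O1 - RP_O2 on [1, dP, d|R|], per (train bin, task bin).

    Cells where censoring leaves fewer than three valid trials, or where the
    regressors are collinear over the valid trials, are NaN.  The safe
    outcome's mean reactivation over valid trials is returned alongside.
    """
    n_trials, _, n_train, n_task = tensor.rp.shape
    if len(trials) != n_trials:
        raise ValueError("design trials and tensor disagree on trial count")
    reg = trial_regressors(trials)
    d_rp = tensor.rp[:, 0] - tensor.rp[:, 1]  # (n_trials, n_train, n_task)
    rp_os = tensor.rp[:, 2]

    beta_prob = np.full((n_train, n_task), np.nan)
    beta_rew = np.full((n_train, n_task), np.nan)
    rp_os_mean = np.full((n_train, n_task), np.nan)
    for j in range(n_task):
        valid = tensor.mask[:, j]
        n_valid = int(valid.sum())
        if n_valid < MIN_TRIALS_PER_CELL:
            continue
        X = np.column_stack([np.ones(n_valid), reg[valid]])
        if np.linalg.matrix_rank(X) < 3:
            continue
        Y = d_rp[valid, :, j]  # (n_valid, n_train)
        coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
        beta_prob[:, j] = coef[1]
        beta_rew[:, j] = coef[2]
        rp_os_mean[:, j] = rp_os[valid, :, j].mean(axis=0)
    return PrioritizationMaps(
        beta_prob=beta_prob,
        beta_rew=beta_rew,
        rp_os_mean=rp_os_mean,
        train_times_ms=tensor.train_times_ms.copy(),
        task_times_ms=tensor.task_times_ms.copy(),
    )
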