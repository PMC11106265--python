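"""Synthetic cohorts with recoverable ground truth for every pipeline stage.

The generator emulates (i) the risky-choice task design, (ii) choices drawn
from any implemented choice model at known per-subject parameters, (iii)
localizer and choice-period sensor epochs in which each stimulus has a
planted spatial pattern under a temporal envelope, with task-period
reactivation strength that depends linearly on trial probability and
absolute reward, and (iv) probe response times with plantable log-RT
effects.  Between-subject couplings tie each subject's behavioral weights to
their planted neural prioritization slopes and RT slopes, mirroring the
statistical structure the second-level analyses estimate.

Every bundle is fully reproducible from (spec, master seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .decode import EpochSet, ITI_LABEL, STIMULUS_VOCABULARY
from .models import ChoiceObservation, ModelParams, simulate_choices
from .rtprobe import ProbeTrial
from .task import TaskDesign, generate_task

__all__ = [
    "CohortSpec",
    "SubjectBundle",
    "CohortBundle",
    "simulate_localizer",
    "simulate_task_meg",
    "simulate_cohort",
    "simulate_probe_cohort",
]

REWARD_SCALE = 30.0  # points; normalizes absolute-reward contrasts internally


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort.

    Defaults mirror the study's scale: 19 subjects with 288 decision trials
    each for the sensor-level arm and 88 subjects for the RT-probe arm.
    ``pattern_snr`` is the planted-pattern amplitude relative to unit sensor
    noise; couplings ``a_*`` link behavioral choice weights to planted
    neural prioritization slopes, ``b_*`` to planted RT slopes (negative RT
    effects for positive weights), and ``bis_coupling`` links the
    impulsivity covariate negatively to probability prioritization.
    """

    n_subjects: int = 19
    n_subjects_rt: int = 88
    n_sensors: int = 120

    # localizer geometry: 3 blocks x 7 stimuli x 20 presentations
    n_localizer_blocks: int = 3
    n_reps_per_block: int = 20
    localizer_times_ms: tuple = tuple(range(10, 501, 10))
    task_times_ms: tuple = tuple(range(0, 501, 10))

    pattern_snr: float = 2.0
    code_center_ms: float = 200.0
    temporal_code_width_ms: float = 50.0
    task_locus_ms: float = 250.0
    task_locus_width_ms: float = 50.0
    base_gain: float = 1.0

    # choice-weight population (additive heuristic model)
    mu_beta_gain: float = 0.2
    mu_beta_loss: float = -0.2
    sd_beta0: float = 0.5
    mu_beta_prob: float = 4.0
    sd_beta_prob: float = 1.5
    mu_beta_rew: float = 0.06
    sd_beta_rew: float = 0.025

    # behavioral-neural and behavioral-RT couplings (standardized scales)
    a_prob: float = 1.0
    a_rew: float = 1.0
    slope_noise: float = 0.25
    b_prob: float = 0.15
    b_rew: float = 0.15
    rt_slope_noise: float = 0.05
    rt_resid_sd: float = 0.2
    rt_base_s: float = 0.5
    bis_base: float = 60.0
    bis_coupling: float = 5.0
    bis_noise: float = 3.0

    # response times in the choice task (shifted lognormal)
    choice_rt_shift_s: float = 0.25
    choice_rt_mu: float = np.log(0.5)
    choice_rt_sigma: float = 0.35

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.pattern_snr <= 0:
            raise ValueError("pattern_snr must be positive")


@dataclass
class SubjectBundle:
    subject: int
    design: TaskDesign
    choices: list  # list[ChoiceObservation]
    localizer: EpochSet | None = None
    task_epochs: EpochSet | None = None
    responses_s: np.ndarray | None = None
    probe_trials: list = field(default_factory=list)


@dataclass
class CohortBundle:
    spec: CohortSpec
    subjects: list  # list[SubjectBundle]
    covariates: pd.DataFrame  # indexed by subject: bis, true weights/slopes
    truth: dict  # ground-truth manifest (JSON-serializable)

    def choice_cohort(self) -> list:
        return [s.choices for s in self.subjects]

    def write_truth(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.truth, f, indent=2)


def _subject_rng(spec: CohortSpec, subject: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed % (2**31), subject, stream])


def _patterns(spec: CohortSpec, subject: int) -> dict[str, np.ndarray]:
    """Fixed random sensor pattern per stimulus, shared by localizer and task."""
    rng = _subject_rng(spec, subject, 9)
    return {s: rng.normal(0, 1, spec.n_sensors) for s in STIMULUS_VOCABULARY}


def _envelope(times_ms: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((times_ms - center) / width) ** 2)


def simulate_localizer(spec: CohortSpec, subject: int) -> EpochSet:
    """Localizer epochs: blocks x stimuli x presentations plus ITI segments.

    Each stimulus event carries its planted sensor pattern under a Gaussian
    temporal envelope at amplitude ``pattern_snr``; ITI events are pure unit
    noise, matched in number to the stimulus events.
    """
    rng = _subject_rng(spec, subject, 1)
    patterns = _patterns(spec, subject)
    times = np.asarray(spec.localizer_times_ms, float)
    env = _envelope(times, spec.code_center_ms, spec.temporal_code_width_ms)

    labels = []
    for _block in range(spec.n_localizer_blocks):
        block_labels = list(STIMULUS_VOCABULARY) * spec.n_reps_per_block
        order = rng.permutation(len(block_labels))
        labels.extend(block_labels[i] for i in order)
    n_stim_events = len(labels)
    labels.extend([ITI_LABEL] * n_stim_events)

    data = rng.normal(0, 1, (spec.n_sensors, len(times), len(labels)))
    for e, lab in enumerate(labels):
        if lab == ITI_LABEL:
            continue
        data[:, :, e] += spec.pattern_snr * np.outer(patterns[lab], env)
    return EpochSet(
        data=data,
        event_labels=np.array(labels, dtype=object),
        times_ms=times,
        alignment="stimulus",
    )


def simulate_task_meg(
    spec: CohortSpec,
    subject: int,
    design: TaskDesign,
    slope_prob: float,
    slope_rew: float,
) -> tuple[EpochSet, np.ndarray]:
    """Choice-period epochs with planted, graded outcome reactivation.

    Per decision trial, each outcome's pattern is injected at the task
    locus with gain ``base + slope_prob*(P_Ox - .5) +
    slope_rew*(|R_Ox| - mean|R|)/REWARD_SCALE`` (safe outcome: base gain
    only).  Response times are shifted-lognormal; bins after the response
    are still simulated but are censored downstream.
    """
    rng = _subject_rng(spec, subject, 2)
    patterns = _patterns(spec, subject)
    times = np.asarray(spec.task_times_ms, float)
    env = _envelope(times, spec.task_locus_ms, spec.task_locus_width_ms)
    trials = design.decision_trials
    n_trials = len(trials)

    data = rng.normal(0, 1, (spec.n_sensors, len(times), n_trials))
    mean_abs_r = float(np.mean([[abs(t.r_O1), abs(t.r_O2)] for t in trials]))
    for i, t in enumerate(trials):
        for stim, p_x, r_x in (
            ("O1", t.p_O1, t.r_O1),
            ("O2", t.p_O2, t.r_O2),
            ("OS", None, t.r_OS),
        ):
            gain = spec.base_gain
            if p_x is not None:
                gain += slope_prob * (p_x - 0.5)
                gain += slope_rew * (abs(r_x) - mean_abs_r) / REWARD_SCALE
            data[:, :, i] += spec.pattern_snr * gain * np.outer(patterns[stim], env)
    rts = spec.choice_rt_shift_s + rng.lognormal(
        spec.choice_rt_mu, spec.choice_rt_sigma, n_trials
    )
    epochs = EpochSet(
        data=data,
        event_labels=np.array(["trial"] * n_trials, dtype=object),
        times_ms=times,
        alignment="probability_stimulus",
    )
    return epochs, rts


def _draw_choice_params(spec: CohortSpec, rng: np.random.Generator, n: int):
    bp = rng.normal(spec.mu_beta_prob, spec.sd_beta_prob, n)
    bw = rng.normal(spec.mu_beta_rew, spec.sd_beta_rew, n)
    bg = rng.normal(spec.mu_beta_gain, spec.sd_beta0, n)
    bl = rng.normal(spec.mu_beta_loss, spec.sd_beta0, n)
    return bp, bw, bg, bl


def _probe_trials_for_subject(
    spec: CohortSpec,
    subject: int,
    design: TaskDesign,
    beta_prob_rt: float,
    beta_rew_rt: float,
    rng: np.random.Generator,
) -> list[ProbeTrial]:
    """Probe RTs from the log-linear generative form, one per probe trial.

    A third of the design's decision trials become probe trials; the probe
    lands on O1, O2 or OS with equal probability (safe probes are emitted
    but carry no probability contrast and are excluded from fits).
    """
    trials = design.decision_trials
    n_probe = len(trials) // 3
    idx = rng.choice(len(trials), size=n_probe, replace=False)
    out = []
    for i in idx:
        t = trials[i]
        probed = ("O1", "O2", "OS")[rng.integers(3)]
        if probed == "OS":
            dp, dr = 0.0, 0.0
            p_pr = p_np = np.nan
            r_pr, r_np = abs(t.r_OS), np.nan
        elif probed == "O1":
            p_pr, p_np = t.p_O1, t.p_O2
            r_pr, r_np = abs(t.r_O1), abs(t.r_O2)
            dp, dr = p_pr - p_np, r_pr - r_np
        else:
            p_pr, p_np = t.p_O2, t.p_O1
            r_pr, r_np = abs(t.r_O2), abs(t.r_O1)
            dp, dr = p_pr - p_np, r_pr - r_np
        log_rt = (
            np.log(spec.rt_base_s)
            + beta_prob_rt * dp
            + (beta_rew_rt / REWARD_SCALE) * dr
            + rng.normal(0, spec.rt_resid_sd)
        )
        out.append(
            ProbeTrial(
                subject=subject,
                probed_stimulus=probed,
                p_probed=p_pr,
                p_nonprobed=p_np,
                abs_r_probed=r_pr,
                abs_r_nonprobed=r_np,
                rt=float(np.exp(log_rt)),
            )
        )
    return out


def simulate_cohort(spec: CohortSpec, with_epochs: bool = True) -> CohortBundle:
    """Simulate the sensor-level cohort: choices, epochs, covariates, truth.

    Per-subject choice weights are drawn from the population Gaussians;
    planted neural slopes equal the coupling times the standardized weight
    plus noise; the impulsivity covariate couples negatively to the planted
    probability-prioritization slope.
    """
    rng = np.random.default_rng([spec.seed % (2**31), 777])
    n = spec.n_subjects
    bp, bw, bg, bl = _draw_choice_params(spec, rng, n)
    z_prob = (bp - spec.mu_beta_prob) / spec.sd_beta_prob
    z_rew = (bw - spec.mu_beta_rew) / spec.sd_beta_rew
    slope_prob = spec.a_prob * z_prob + rng.normal(0, spec.slope_noise, n)
    slope_rew = spec.a_rew * z_rew + rng.normal(0, spec.slope_noise, n)
    bis = spec.bis_base - spec.bis_coupling * slope_prob + rng.normal(0, spec.bis_noise, n)

    subjects = []
    for s in range(n):
        design = generate_task(seed=spec.seed % (2**31) + 10_000 + s, variant="meg")
        params = ModelParams(
            "additive",
            {"beta_gain": bg[s], "beta_loss": bl[s], "beta_prob": bp[s], "beta_rew": bw[s]},
        )
        choices = simulate_choices(params, design, seed=spec.seed % (2**31) + 20_000 + s)
        bundle = SubjectBundle(subject=s, design=design, choices=choices)
        if with_epochs:
            bundle.localizer = simulate_localizer(spec, s)
            bundle.task_epochs, bundle.responses_s = simulate_task_meg(
                spec, s, design, slope_prob[s], slope_rew[s]
            )
        subjects.append(bundle)

    covariates = pd.DataFrame(
        {
            "bis": bis,
            "true_beta_prob": bp,
            "true_beta_rew": bw,
            "true_beta_gain": bg,
            "true_beta_loss": bl,
            "true_slope_prob": slope_prob,
            "true_slope_rew": slope_rew,
        },
        index=pd.RangeIndex(n, name="subject"),
    )
    truth = {
        "spec": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(spec).items()},
        "subjects": covariates.reset_index().to_dict(orient="records"),
    }
    return CohortBundle(spec=spec, subjects=subjects, covariates=covariates, truth=truth)


def simulate_probe_cohort(spec: CohortSpec) -> CohortBundle:
    """Simulate the behavior-only RT-probe cohort (choices + probe RTs).

    Per-subject RT slopes couple negatively to the choice weights:
    beta_prob_rt = -b_prob * z(beta_prob) + noise, and likewise for reward.
    """
    rng = np.random.default_rng([spec.seed % (2**31), 888])
    n = spec.n_subjects_rt
    bp, bw, bg, bl = _draw_choice_params(spec, rng, n)
    z_prob = (bp - spec.mu_beta_prob) / spec.sd_beta_prob
    z_rew = (bw - spec.mu_beta_rew) / spec.sd_beta_rew
    bprt = -spec.b_prob * z_prob + rng.normal(0, spec.rt_slope_noise, n)
    brrt = -spec.b_rew * z_rew + rng.normal(0, spec.rt_slope_noise, n)

    subjects = []
    for s in range(n):
        design = generate_task(seed=spec.seed % (2**31) + 50_000 + s, variant="online")
        params = ModelParams(
            "additive",
            {"beta_gain": bg[s], "beta_loss": bl[s], "beta_prob": bp[s], "beta_rew": bw[s]},
        )
        choices = simulate_choices(params, design, seed=spec.seed % (2**31) + 60_000 + s)
        probe_rng = _subject_rng(spec, s, 3)
        probes = _probe_trials_for_subject(spec, s, design, bprt[s], brrt[s], probe_rng)
        subjects.append(
            SubjectBundle(subject=s, design=design, choices=choices, probe_trials=probes)
        )
    covariates = pd.DataFrame(
        {
            "true_beta_prob": bp,
            "true_beta_rew": bw,
            "true_beta_prob_rt": bprt,
            "true_beta_rew_rt": brrt,
        },
        index=pd.RangeIndex(n, name="subject"),
    )
    truth = {
        "spec": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(spec).items()},
        "subjects": covariates.reset_index().to_dict(orient="records"),
    }
    return CohortBundle(spec=spec, subjects=subjects, covariates=covariates, truth=truth)
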