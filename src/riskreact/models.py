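"""Choice models for the accept/reject gamble task.

Five models map a trial to an acceptance probability:

* ``ev`` -- softmax on the expected-value difference between accepting and
  rejecting, ``logistic(beta * [P_O1*R_O1 + P_O2*R_O2 - R_OS])``.
* ``additive`` -- the additive heuristic: a linear integration of a
  probability comparison (chance of the better vs worse gamble outcome) and a
  reward comparison (gamble reward midpoint vs safe reward, both baseline
  corrected), plus a frame-specific intercept.
* ``prospect`` -- probability weighting (log-odds linear) and power utility
  inside the expected-value rule.
* ``prob_sampling`` / ``utility_sampling`` -- importance-sampling evaluators:
  the decision maker draws a small number of outcome samples (ordered-probit
  distributed count, max 7) from a proposal q and accepts iff the
  importance-weighted utility-difference estimate is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .task import TaskDesign, TrialSpec, baseline_correct

__all__ = [
    "ChoiceObservation",
    "ModelParams",
    "SamplingConfig",
    "MODEL_PARAM_NAMES",
    "MODEL_TRANSFORMS",
    "p_accept_ev",
    "p_accept_additive",
    "weight_logodds",
    "utility",
    "p_accept_prospect",
    "ordered_probit_pmf",
    "p_accept_sampling",
    "p_accept",
    "loglik",
    "simulate_choices",
]

P_CLAMP = 1e-12  # likelihood clamp away from {0, 1}

#: parameter names per model, in canonical order
MODEL_PARAM_NAMES = {
    "ev": ("beta",),
    "additive": ("beta_gain", "beta_loss", "beta_prob", "beta_rew"),
    "prospect": ("beta", "alpha_gain", "alpha_loss", "delta", "gamma"),
    "prob_sampling": ("n", "alpha_gain", "alpha_loss"),
    "utility_sampling": ("n", "alpha_gain", "alpha_loss"),
}

#: link used to map each parameter to an unconstrained scale for hierarchical
#: fitting: "identity" or "log" (positivity constraint)
MODEL_TRANSFORMS = {
    "ev": {"beta": "log"},
    "additive": {p: "identity" for p in MODEL_PARAM_NAMES["additive"]},
    "prospect": {p: "log" for p in MODEL_PARAM_NAMES["prospect"]},
    "prob_sampling": {"n": "identity", "alpha_gain": "log", "alpha_loss": "log"},
    "utility_sampling": {"n": "identity", "alpha_gain": "log", "alpha_loss": "log"},
}


@dataclass
class ChoiceObservation:
    trial: TrialSpec
    accept: int

    def __post_init__(self) -> None:
        if self.accept not in (0, 1):
            raise ValueError("accept must be 0 or 1")
        if self.trial.is_catch:
            raise ValueError("choice observations must be non-catch trials")


@dataclass
class ModelParams:
    """Named parameter vector for one choice model."""

    model_id: str
    values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = MODEL_PARAM_NAMES.get(self.model_id)
        if names is None:
            raise ValueError(f"unknown model {self.model_id!r}")
        missing = set(names) - set(self.values)
        if missing:
            raise ValueError(f"missing parameters for {self.model_id}: {sorted(missing)}")
        for p, link in MODEL_TRANSFORMS[self.model_id].items():
            if link == "log" and self.values[p] < 0:
                raise ValueError(f"parameter {p} must be non-negative")

    def __getitem__(self, name: str) -> float:
        return self.values[name]


@dataclass
class SamplingConfig:
    """Sample-count distribution for the sampling models."""

    S_max: int = 7
    c: float = 2.0

    def __post_init__(self) -> None:
        if self.S_max < 1 or self.c <= 0:
            raise ValueError("invalid sampling configuration")


def _check_non_catch(trial: TrialSpec) -> None:
    if trial.is_catch:
        raise ValueError("acceptance probability undefined for catch trials")


def p_accept_ev(trial: TrialSpec, params: ModelParams) -> float:
    _check_non_catch(trial)
    ev_diff = trial.p_O1 * trial.r_O1 + trial.p_O2 * trial.r_O2 - trial.r_OS
    return float(expit(params["beta"] * ev_diff))


def p_accept_additive(trial: TrialSpec, params: ModelParams) -> float:
    _check_non_catch(trial)
    beta0 = params["beta_gain"] if trial.frame == "gain" else params["beta_loss"]
    if trial.r_O1 > trial.r_O2:
        p_better, p_worse = trial.p_O1, trial.p_O2
    elif trial.r_O2 > trial.r_O1:
        p_better, p_worse = trial.p_O2, trial.p_O1
    else:  # reward tie cannot occur in generated designs; defensive
        p_better = p_worse = 0.5
    r_trig, r_safe = baseline_correct(trial)
    z = (
        beta0
        + params["beta_prob"] * (p_better - p_worse)
        + params["beta_rew"] * (r_trig / 2.0 - r_safe)
    )
    return float(expit(z))


def weight_logodds(p, delta: float, gamma: float):
    """Log-odds linear probability weighting, w(p) = d p^g / (d p^g + (1-p)^g)."""
    if delta <= 0 or gamma <= 0:
        raise ValueError("delta and gamma must be positive")
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p must lie in [0, 1]")
    num = delta * p**gamma
    out = num / (num + (1.0 - p) ** gamma)
    return float(out) if out.ndim == 0 else out


def utility(x, alpha_gain: float, alpha_loss: float):
    """Power utility: x^a_gain for x >= 0, -(|x|^a_loss) for x < 0."""
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):  # extreme alphas arise during optimization
        out = np.where(x >= 0, np.abs(x) ** alpha_gain, -(np.abs(x) ** alpha_loss))
    return float(out) if out.ndim == 0 else out


def p_accept_prospect(trial: TrialSpec, params: ModelParams) -> float:
    _check_non_catch(trial)
    ag, al = params["alpha_gain"], params["alpha_loss"]
    w1 = weight_logodds(trial.p_O1, params["delta"], params["gamma"])
    w2 = weight_logodds(trial.p_O2, params["delta"], params["gamma"])
    z = (
        w1 * utility(trial.r_O1, ag, al)
        + w2 * utility(trial.r_O2, ag, al)
        - utility(trial.r_OS, ag, al)
    )
    return float(expit(params["beta"] * z))


def ordered_probit_pmf(n: float, cfg: SamplingConfig | None = None) -> np.ndarray:
    """pmf of the sample count S over {1..S_max}.

    P(S=s) is proportional to Phi((s+1/2-n)/c) - Phi((s-1/2-n)/c),
    renormalized over the support; unimodal with mode tracking n.
    """
    cfg = cfg or SamplingConfig()
    s = np.arange(1, cfg.S_max + 1)
    raw = norm.cdf((s + 0.5 - n) / cfg.c) - norm.cdf((s - 0.5 - n) / cfg.c)
    total = raw.sum()
    if total <= 0.0:  # n far outside the support: all mass on the nearest count
        out = np.zeros(cfg.S_max)
        out[int(np.clip(round(n), 1, cfg.S_max)) - 1] = 1.0
        return out
    return raw / total


def _sampling_proposal(trial: TrialSpec, params: ModelParams, variant: str) -> float:
    """q(O1) for the sampling models."""
    p1, p2 = trial.p_O1, trial.p_O2
    if variant == "probability":
        a1, a2 = p1, p2
    elif variant == "utility_weighted":
        ag, al = params["alpha_gain"], params["alpha_loss"]
        vs = utility(trial.r_OS, ag, al)
        a1 = p1 * abs(utility(trial.r_O1, ag, al) - vs)
        a2 = p2 * abs(utility(trial.r_O2, ag, al) - vs)
        if a1 + a2 == 0.0:  # both gamble utilities equal the safe utility
            a1, a2 = p1, p2
    else:
        raise ValueError(f"unknown sampling variant {variant!r}")
    return a1 / (a1 + a2)


def p_accept_sampling(
    trial: TrialSpec,
    params: ModelParams,
    cfg: SamplingConfig | None = None,
    variant: str | None = None,
    normalizer: str = "count",
) -> float:
    """Marginal acceptance probability of an importance-sampling evaluator.

    Marginalizes over the sample count S (ordered probit) and the number of
    O1 draws (binomial under the proposal q).  Given a sample composition the
    utility-difference estimate is

        E(n1, S) = [n1 w1 dv1 + (S-n1) w2 dv2] / [n1 w1 + (S-n1) w2]

    with importance weights w_i = P_Oi / q(Oi) and dv_i = v(R_Oi) - v(R_OS);
    the gamble is accepted iff E > 0 (ties split 50/50).  ``normalizer``
    selects the count-based denominator above (default) or the literal
    proportion form ``n1 w1 + (1-n1) w2``.
    """
    _check_non_catch(trial)
    if variant is None:
        variant = "probability" if params.model_id == "prob_sampling" else "utility_weighted"
    cfg = cfg or SamplingConfig()
    ag, al = params["alpha_gain"], params["alpha_loss"]
    vs = utility(trial.r_OS, ag, al)
    dv1 = utility(trial.r_O1, ag, al) - vs
    dv2 = utility(trial.r_O2, ag, al) - vs
    q1 = _sampling_proposal(trial, params, variant)
    q2 = 1.0 - q1
    # degenerate proposals: all samples come from one outcome
    if q1 == 0.0 or q1 == 1.0:
        dv = dv1 if q1 == 1.0 else dv2
        return 1.0 if dv > 0 else (0.0 if dv < 0 else 0.5)
    w1 = trial.p_O1 / q1
    w2 = trial.p_O2 / q2
    pmf_S = ordered_probit_pmf(params["n"], cfg)
    total = 0.0
    from scipy.stats import binom

    for S, pS in zip(range(1, cfg.S_max + 1), pmf_S):
        n1 = np.arange(S + 1)
        if normalizer == "count":
            denom = n1 * w1 + (S - n1) * w2
            num = n1 * w1 * dv1 + (S - n1) * w2 * dv2
        else:  # literal printed proportion form
            denom = n1 * w1 + (1 - n1) * w2
            num = n1 * w1 * dv1 + (1 - n1) * w2 * dv2
        # a balanced composition can be an exact mathematical tie (the
        # utility-weighted proposal equalizes |w * dv| across outcomes), so
        # zero is detected at a relative tolerance before taking the sign
        mag = n1 * np.abs(w1 * dv1) + np.abs(S - n1) * np.abs(w2 * dv2)
        tol = 1e-9 * mag
        num_sign = np.where(num > tol, 1.0, np.where(num < -tol, -1.0, 0.0))
        e_sign = num_sign * np.sign(denom)
        p_acc = np.where(e_sign > 0, 1.0, np.where(e_sign < 0, 0.0, 0.5))
        total += pS * float(binom.pmf(n1, S, q1) @ p_acc)
    return float(total)


_P_ACCEPT = {
    "ev": p_accept_ev,
    "additive": p_accept_additive,
    "prospect": p_accept_prospect,
    "prob_sampling": p_accept_sampling,
    "utility_sampling": p_accept_sampling,
}


def p_accept(trial: TrialSpec, params: ModelParams, **kwargs) -> float:
    """Dispatch to the acceptance-probability function for ``params.model_id``."""
    return _P_ACCEPT[params.model_id](trial, params, **kwargs)


def loglik(params: ModelParams, data: list[ChoiceObservation]) -> float:
    """Bernoulli log likelihood of accept/reject choices under a model."""
    total = 0.0
    for obs in data:
        p = np.clip(p_accept(obs.trial, params), P_CLAMP, 1.0 - P_CLAMP)
        total += np.log(p) if obs.accept else np.log(1.0 - p)
    return float(total)


def simulate_choices(
    params: ModelParams, design: TaskDesign, seed: int
) -> list[ChoiceObservation]:
    """Draw accept ~ Bernoulli(p_accept) for every non-catch trial."""
    rng = np.random.default_rng(seed)
    out = []
    for trial in design.decision_trials:
        p = p_accept(trial, params)
        out.append(ChoiceObservation(trial=trial, accept=int(rng.random() < p)))
    return out
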