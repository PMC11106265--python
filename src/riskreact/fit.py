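"""Hierarchical fitting of choice models and model comparison by iBIC.

Each subject's parameters are fit by maximum a posteriori under a group-level
Gaussian prior on transformed (unconstrained) parameters; the prior itself is
updated from the subjects' Laplace-approximated posteriors.  Alternating
these steps is an Expectation-Maximization scheme whose objective, the
approximate log marginal likelihood of the cohort, is monitored for
convergence.  Models are compared by the integrated Bayesian information
criterion (iBIC): minus twice the summed per-subject log marginal likelihood
(estimated by Monte-Carlo draws from the fitted prior) plus a complexity
penalty counting the group-level hyperparameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from .models import (
    MODEL_PARAM_NAMES,
    MODEL_TRANSFORMS,
    ChoiceObservation,
    ModelParams,
    P_CLAMP,
    SamplingConfig,
    p_accept,
)
from .task import TaskDesign, baseline_correct

__all__ = ["GroupPrior", "FitResult", "fit_em", "ibic", "predicted_acceptance"]

VARIANCE_FLOOR = 1e-6
N_RESTARTS = 5
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 200


@dataclass
class GroupPrior:
    """Independent Gaussian prior per transformed parameter."""

    names: tuple
    mean: np.ndarray
    variance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, float)
        self.variance = np.asarray(self.variance, float)
        if np.any(self.variance <= 0):
            raise ValueError("prior variances must be positive")


@dataclass
class FitResult:
    model_id: str
    subject_params: list  # list[ModelParams] on the natural scale
    subject_means: np.ndarray  # (n_subjects, k) transformed-scale MAP
    subject_covs: np.ndarray  # (n_subjects, k, k) Laplace covariances
    prior: GroupPrior
    trace: list = field(default_factory=list)
    converged: bool = True
    warnings: list = field(default_factory=list)
    ibic: float | None = None

    def param_series(self, name: str) -> np.ndarray:
        """Natural-scale values of one parameter across subjects."""
        return np.array([p[name] for p in self.subject_params])


# ---------------------------------------------------------------------------
# transformed <-> natural parameter scales


def _links(model_id: str) -> list[str]:
    return [MODEL_TRANSFORMS[model_id][p] for p in MODEL_PARAM_NAMES[model_id]]


def to_natural(model_id: str, x: np.ndarray) -> np.ndarray:
    links = _links(model_id)
    out = np.array(x, float, copy=True)
    for i, link in enumerate(links):
        if link == "log":
            out[..., i] = np.exp(np.clip(x[..., i], -50, 50))
    names = MODEL_PARAM_NAMES[model_id]
    if "n" in names:  # sample-count center clipped to its meaningful range
        i = names.index("n")
        out[..., i] = np.clip(out[..., i], 0.0, SamplingConfig().S_max + 1.0)
    return out


def natural_params(model_id: str, x: np.ndarray) -> ModelParams:
    vals = to_natural(model_id, np.asarray(x, float))
    return ModelParams(model_id, dict(zip(MODEL_PARAM_NAMES[model_id], vals)))


# ---------------------------------------------------------------------------
# fast likelihood paths.  The ev and additive models are generalized linear:
# the decision variable is X @ w with w the natural parameters (ev: w = [beta]
# times the expected-value difference feature).


def glm_features(model_id: str, data: list[ChoiceObservation]):
    """(X, y) such that the decision variable is X @ natural_params, or None."""
    if model_id not in ("ev", "additive"):
        return None
    rows, y = [], []
    for obs in data:
        t = obs.trial
        y.append(obs.accept)
        if model_id == "ev":
            rows.append([t.p_O1 * t.r_O1 + t.p_O2 * t.r_O2 - t.r_OS])
        else:
            if t.r_O1 > t.r_O2:
                dp = t.p_O1 - t.p_O2
            elif t.r_O2 > t.r_O1:
                dp = t.p_O2 - t.p_O1
            else:
                dp = 0.0
            r_trig, r_safe = baseline_correct(t)
            is_gain = 1.0 if t.frame == "gain" else 0.0
            rows.append([is_gain, 1.0 - is_gain, dp, r_trig / 2.0 - r_safe])
    return np.asarray(rows, float), np.asarray(y, float)


class SubjectLikelihood:
    """Per-subject log likelihood with a vectorized path for GLM models."""

    def __init__(self, model_id: str, data: list[ChoiceObservation]):
        self.model_id = model_id
        self.data = data
        self.n_obs = len(data)
        feats = glm_features(model_id, data)
        self._X, self._y = feats if feats is not None else (None, None)

    def loglik_trans(self, x: np.ndarray) -> float:
        """Log likelihood at transformed parameters x."""
        w = to_natural(self.model_id, np.asarray(x, float))
        if self._X is not None:
            p = np.clip(expit(self._X @ w), P_CLAMP, 1 - P_CLAMP)
            return float(self._y @ np.log(p) + (1 - self._y) @ np.log(1 - p))
        params = ModelParams(self.model_id, dict(zip(MODEL_PARAM_NAMES[self.model_id], w)))
        total = 0.0
        for obs in self.data:
            p = np.clip(p_accept(obs.trial, params), P_CLAMP, 1 - P_CLAMP)
            total += np.log(p) if obs.accept else np.log(1 - p)
        return float(total)

    def loglik_many(self, xs: np.ndarray) -> np.ndarray:
        """Log likelihood at each row of transformed draws (n_draws, k)."""
        xs = np.asarray(xs, float)
        if self._X is not None:
            W = to_natural(self.model_id, xs)  # (n_draws, k)
            Z = self._X @ W.T  # (n_obs, n_draws)
            P = np.clip(expit(Z), P_CLAMP, 1 - P_CLAMP)
            return self._y @ np.log(P) + (1 - self._y) @ np.log(1 - P)
        return np.array([self.loglik_trans(x) for x in xs])


# ---------------------------------------------------------------------------
# E-step machinery


def _neg_log_post(x, lik: SubjectLikelihood, prior: GroupPrior) -> float:
    lp = -0.5 * np.sum((x - prior.mean) ** 2 / prior.variance)
    lp -= 0.5 * np.sum(np.log(2 * np.pi * prior.variance))
    return -(lik.loglik_trans(x) + lp)


def _numerical_hessian(f, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    k = len(x)
    H = np.empty((k, k))
    hs = step * np.maximum(1.0, np.abs(x))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = hs[i]
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / hs[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = hs[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * hs[i] * hs[j])
    return H


def _map_estimate(lik, prior, starts):
    best = None
    for x0 in starts:
        res = minimize(
            _neg_log_post, x0, args=(lik, prior), method="L-BFGS-B",
            options={"ftol": 1e-12, "gtol": 1e-9, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best


def _laplace_cov(lik, prior, x_map):
    H = _numerical_hessian(lambda x: _neg_log_post(x, lik, prior), x_map)
    # symmetrize and guard against non-positive-definite curvature
    H = 0.5 * (H + H.T)
    try:
        evals, evecs = np.linalg.eigh(H)
    except np.linalg.LinAlgError:
        return np.diag(prior.variance), False
    ok = bool(np.all(evals > 0))
    evals = np.clip(evals, 1e-8, None)
    cov = (evecs / evals) @ evecs.T
    return cov, ok


def fit_em(
    model_id: str,
    cohort: list,
    seed: int = 0,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    n_restarts: int = N_RESTARTS,
    init_prior: GroupPrior | None = None,
) -> FitResult:
    """Fit a choice model to a cohort by hierarchical EM.

    ``cohort`` is a list of per-subject ``ChoiceObservation`` lists.  The
    E-step computes each subject's MAP estimate and Laplace covariance under
    the current Gaussian prior (seeded random restarts on the first
    iteration, warm starts afterwards); the M-step updates the prior moments
    from the subject posteriors (variance floored).  Iterates until the
    change in the approximate log marginal likelihood falls below ``tol``.
    """
    names = MODEL_PARAM_NAMES[model_id]
    k = len(names)
    if any(len(s) == 0 for s in cohort):
        raise ValueError("every subject needs at least one observation")
    liks = [SubjectLikelihood(model_id, s) for s in cohort]
    rng = np.random.default_rng(seed)

    if init_prior is None:
        prior = GroupPrior(names, np.zeros(k), np.full(k, 10.0))
    else:
        prior = GroupPrior(names, init_prior.mean.copy(), init_prior.variance.copy())

    means = np.zeros((len(liks), k))
    covs = np.tile(np.eye(k), (len(liks), 1, 1))
    trace: list[float] = []
    warnings: list[str] = []
    converged = False

    for iteration in range(max_iter):
        objective = 0.0
        for s, lik in enumerate(liks):
            if iteration == 0:
                starts = [prior.mean.copy()]
                starts += list(prior.mean + rng.normal(0, 1, size=(n_restarts - 1, k)))
            else:
                starts = [means[s]]
            res = _map_estimate(lik, prior, starts)
            means[s] = res.x
            cov, ok = _laplace_cov(lik, prior, res.x)
            covs[s] = cov
            if not ok:
                msg = f"subject {s}: non-positive-definite Hessian at iteration {iteration}"
                warnings.append(msg)
            sign, logdet = np.linalg.slogdet(cov)
            objective += -res.fun + 0.5 * (k * np.log(2 * np.pi) + logdet)
        trace.append(float(objective))

        new_mean = means.mean(axis=0)
        second = (means**2 + np.array([np.diag(c) for c in covs])).mean(axis=0)
        new_var = np.maximum(second - new_mean**2, VARIANCE_FLOOR)
        prior = GroupPrior(names, new_mean, new_var)

        if iteration > 0 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
    if not converged:
        warnings.append("EM did not converge within max_iter")

    subject_params = [natural_params(model_id, m) for m in means]
    return FitResult(
        model_id=model_id,
        subject_params=subject_params,
        subject_means=means.copy(),
        subject_covs=covs.copy(),
        prior=prior,
        trace=trace,
        converged=converged,
        warnings=warnings,
    )


def ibic(fit: FitResult, cohort: list, n_draws: int = 2000, seed: int = 0) -> float:
    """Integrated BIC of a fitted hierarchy.

    -2 * sum_s log p(data_s | prior) + k_prior * log(N_total_choices), with
    the per-subject marginal likelihood estimated by averaging the data
    likelihood over seeded draws from the fitted group prior.
    """
    rng = np.random.default_rng(seed)
    k = len(fit.prior.mean)
    n_total = sum(len(s) for s in cohort)
    total = 0.0
    for subj in cohort:
        lik = SubjectLikelihood(fit.model_id, subj)
        draws = fit.prior.mean + rng.normal(0, 1, size=(n_draws, k)) * np.sqrt(
            fit.prior.variance
        )
        lls = lik.loglik_many(draws)
        total += logsumexp(lls) - np.log(n_draws)
    return float(-2.0 * total + 2 * k * np.log(n_total))


def predicted_acceptance(fit: FitResult, design: TaskDesign) -> pd.DataFrame:
    """Per subject x trial acceptance probability under the MAP parameters."""
    trials = design.decision_trials
    rows = {}
    for s, params in enumerate(fit.subject_params):
        rows[s] = [p_accept(t, params) for t in trials]
    df = pd.DataFrame(rows).T
    df.index.name = "subject"
    df.columns.name = "trial"
    return df
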