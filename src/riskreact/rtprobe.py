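"""Perceptual-detection response-time probe analysis.

On probe trials an arrowhead appears on one outcome stimulus after the
probability stimulus, and detection latency indexes how actively that
stimulus was being represented.  Per subject, log response time is regressed
on the probed-minus-nonprobed probability difference and absolute-reward
difference (gamble-probe trials only); negative coefficients mean faster
detection of more probable / higher-absolute-reward outcomes.  The
per-subject slopes are then rank-correlated (one-tailed, negative) with the
additive model's choice weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import spearman_onetailed

__all__ = ["ProbeTrial", "fit_rt_weights", "link_rt_to_choice", "RT_BOUNDS_S"]

RT_BOUNDS_S = (0.15, 5.0)  # anticipation / lapse bounds, configurable
GAMBLE_STIMULI = ("O1", "O2")
MIN_TRIALS = 3


@dataclass
class ProbeTrial:
    subject: int
    probed_stimulus: str  # O1 | O2 | OS
    p_probed: float
    p_nonprobed: float
    abs_r_probed: float
    abs_r_nonprobed: float
    rt: float  # seconds


def fit_rt_weights(
    trials: list[ProbeTrial], rt_bounds: tuple[float, float] = RT_BOUNDS_S
) -> pd.DataFrame:
    """Per-subject OLS of log(rt) on probe probability and reward contrasts.

    Only trials probing a gamble outcome enter the fit; non-positive or
    out-of-bounds RTs are dropped with a warning.  Returns a table indexed
    by subject with columns beta_prob_rt, beta_rew_rt, n_trials_used and an
    ``ok`` flag (False when fewer than three usable trials remain).
    """
    lo, hi = rt_bounds
    by_subject: dict[int, list[ProbeTrial]] = {}
    n_dropped = 0
    for tr in trials:
        if tr.probed_stimulus not in GAMBLE_STIMULI:
            continue
        if not (tr.rt > 0 and lo <= tr.rt <= hi):
            n_dropped += 1
            continue
        by_subject.setdefault(tr.subject, []).append(tr)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} probe trials with out-of-bounds RT")

    rows = []
    for subject, subj_trials in sorted(by_subject.items()):
        n = len(subj_trials)
        if n < MIN_TRIALS:
            rows.append(
                {"subject": subject, "beta_prob_rt": np.nan, "beta_rew_rt": np.nan,
                 "n_trials_used": n, "ok": False}
            )
            continue
        dp = np.array([t.p_probed - t.p_nonprobed for t in subj_trials])
        dr = np.array([t.abs_r_probed - t.abs_r_nonprobed for t in subj_trials])
        y = np.log([t.rt for t in subj_trials])
        X = np.column_stack([np.ones(n), dp, dr])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        rows.append(
            {"subject": subject, "beta_prob_rt": coef[1], "beta_rew_rt": coef[2],
             "n_trials_used": n, "ok": True}
        )
    return pd.DataFrame(rows).set_index("subject")


def link_rt_to_choice(
    rt_weights: pd.DataFrame,
    choice_weights: pd.Series,
    pairing: str,
    tail: str = "neg",
) -> tuple[float, float, float]:
    """One-tailed Spearman test pairing RT slopes with choice weights.

    ``pairing`` selects "prob" (beta_prob_rt vs the choice probability
    weight) or "rew" (beta_rew_rt vs the choice reward weight);
    ``choice_weights`` is indexed by subject.
    """
    if pairing not in ("prob", "rew"):
        raise ValueError("pairing must be 'prob' or 'rew'")
    col = "beta_prob_rt" if pairing == "prob" else "beta_rew_rt"
    usable = rt_weights[rt_weights["ok"]]
    common = usable.index.intersection(choice_weights.index)
    if len(common) < 5:
        raise ValueError("need at least 5 subjects with both measures")
    return spearman_onetailed(
        usable.loc[common, col].to_numpy(),
        choice_weights.loc[common].to_numpy(),
        tail=tail,
    )
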